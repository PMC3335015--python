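"""Toy cortical surface meshes and graph-kernel surface smoothing.

The analysis only needs a vertex set with a neighbor structure, so the stand-in
surface is a pair of sphere-like triangulations (one per hemisphere) built from
a seeded rotation of a Fibonacci point set and its convex hull.  Smoothing uses
a Gaussian kernel in graph (hop) distance, normalized per vertex, which plays
the role of a FWHM surface-blurring kernel: on this mesh the FWHM is expressed
in graph-edge units rather than millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from .errors import InvalidArgumentError

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Exact icosahedron (the smallest closed triangulation, every vertex degree 5),
# used verbatim when 12 vertices per hemisphere are requested.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICOSA = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)
_ICOSA /= np.linalg.norm(_ICOSA, axis=1, keepdims=True)


@dataclass
class ToyMesh:
    """Two closed sphere-like hemisphere surfaces with a shared vertex index.

    Attributes
    ----------
    coords : (V, 3) float array of vertex positions (hemispheres offset in x).
    faces : (F, 3) int array of triangles over vertex indices.
    graph : undirected neighbor graph derived from the faces.
    hemisphere : (V,) int array, 0 = left, 1 = right.
    """

    coords: np.ndarray
    faces: np.ndarray
    graph: nx.Graph
    hemisphere: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def edges(self) -> np.ndarray:
        return np.array(sorted(self.graph.edges()), dtype=int)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = ga * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _hemisphere_surface(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    pts = _ICOSA.copy() if n == 12 else _fibonacci_sphere(n)
    rot = Rotation.random(rng=rng).as_matrix()
    pts = pts @ rot.T
    hull = ConvexHull(pts)
    if len(np.unique(hull.simplices)) != n:
        raise InvalidArgumentError(
            "degenerate point set: some vertices fell inside the hull"
        )
    return pts, hull.simplices.astype(int)


def _graph_from_faces(faces: np.ndarray, n_vertices: int) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n_vertices))
    for a, b, c in faces:
        g.add_edge(int(a), int(b))
        g.add_edge(int(b), int(c))
        g.add_edge(int(a), int(c))
    return g


def build_toy_mesh(n_vertices: int, seed: int) -> ToyMesh:
    """Build a two-hemisphere sphere-like triangulated mesh.

    ``n_vertices`` counts vertices per hemisphere (total is twice that).
    Output is deterministic for a fixed seed; each hemisphere is a closed
    surface (V - E + F = 2) and mean vertex degree approaches 6.
    """
    if n_vertices < 12:
        raise InvalidArgumentError("n_vertices must be at least 12 per hemisphere")
    rng = np.random.default_rng(seed)
    coords = []
    faces = []
    hemi = []
    for h, x_offset in enumerate((-2.0, 2.0)):
        pts, tri = _hemisphere_surface(n_vertices, rng)
        pts = pts + np.array([x_offset, 0.0, 0.0])
        coords.append(pts)
        faces.append(tri + h * n_vertices)
        hemi.append(np.full(n_vertices, h, dtype=int))
    coords = np.vstack(coords)
    faces = np.vstack(faces)
    hemisphere = np.concatenate(hemi)
    graph = _graph_from_faces(faces, coords.shape[0])
    return ToyMesh(coords, faces, graph, hemisphere)


def smoothing_matrix(mesh: ToyMesh, fwhm: float) -> np.ndarray:
    """Row-normalized Gaussian graph-distance kernel with the given FWHM.

    Distances are hop counts on the neighbor graph; smoothing never crosses
    hemispheres (their graph distance is infinite).  fwhm = 0 returns the
    identity.
    """
    if fwhm < 0:
        raise InvalidArgumentError("fwhm must be non-negative")
    V = mesh.n_vertices
    if fwhm == 0:
        return np.eye(V)
    adj = nx.to_scipy_sparse_array(mesh.graph, nodelist=range(V), format="csr")
    D = shortest_path(adj, method="D", unweighted=True, directed=False)
    sigma = fwhm * _FWHM_TO_SIGMA
    with np.errstate(over="ignore"):
        W = np.exp(-(D**2) / (2.0 * sigma**2))
    W[~np.isfinite(D)] = 0.0
    W /= W.sum(axis=1, keepdims=True)
    return W


def smooth_on_mesh(values, mesh: ToyMesh, fwhm: float) -> np.ndarray:
    """Smooth one or more per-vertex maps across the mesh surface.

    ``values`` is (V,) or (V, k).  Weights are normalized to sum to one per
    vertex, so a constant map is returned unchanged; the kernel's impulse
    response reaches half maximum at graph distance fwhm / 2.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] != mesh.n_vertices:
        raise InvalidArgumentError("values length must equal mesh vertex count")
    W = smoothing_matrix(mesh, fwhm)
    return W @ v


def default_affected_cluster(mesh: ToyMesh, size: int = 30, start: int = 0) -> np.ndarray:
    """A contiguous vertex cluster grown breadth-first from ``start``.

    Used as the default set of vertices carrying a trajectory peak shift; the
    true spatial extent of such regions is a free simulation parameter.
    """
    if size < 1 or size > mesh.n_vertices:
        raise InvalidArgumentError("cluster size out of range")
    order = [start]
    seen = {start}
    for node in order:
        if len(order) >= size:
            break
        for nb in sorted(mesh.graph.neighbors(node)):
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
                if len(order) >= size:
                    break
    if len(order) < size:
        warnings.warn("hemisphere smaller than requested cluster; truncating")
    return np.array(sorted(order[:size]), dtype=int)
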