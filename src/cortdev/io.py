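"""Plain-text readers and writers for the pipeline's table and mesh formats.

Formats
-------
phenotypes.csv : columns exactly id,diagnosis,age,sex,hand,iq,slice_dummy,med_months
volumes.csv    : id plus one snake_case column per measure
thickness.tsv  : tab-separated; first column id, then v0..v{V-1}; rows in
                 phenotype order
mesh.off       : standard OFF vertex/face format; hemisphere labels are
                 recovered from the face graph's connected components
vertex_stats.tsv : one row per vertex with the trajectory statistics
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .mesh import ToyMesh, _graph_from_faces

PHENOTYPE_COLUMNS = [
    "id", "diagnosis", "age", "sex", "hand", "iq", "slice_dummy", "med_months",
]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in phenotypes.columns]
    if missing:
        raise InvalidArgumentError(f"phenotype table lacks columns {missing}")
    phenotypes[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"{path} lacks columns {missing}")
    return df[PHENOTYPE_COLUMNS]


def write_volumes(volumes: pd.DataFrame, path) -> None:
    volumes.to_csv(path, index=False)


def read_volumes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_thickness(thickness: pd.DataFrame, ids, path) -> None:
    out = thickness.copy()
    out.insert(0, "id", list(ids))
    out.to_csv(path, sep="\t", index=False)


def read_thickness(path) -> tuple[pd.DataFrame, list]:
    df = pd.read_csv(path, sep="\t")
    ids = df["id"].tolist()
    return df.drop(columns=["id"]), ids


def write_mesh_off(mesh: ToyMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for x, y, z in mesh.coords:
            fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")


def read_mesh_off(path) -> ToyMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens or tokens[0] != "OFF":
        raise InvalidArgumentError(f"{path} is not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    coords = np.array(tokens[pos: pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        faces.append([int(t) for t in tokens[pos + 1: pos + 1 + k]])
        pos += 1 + k
    faces = np.array(faces, dtype=int)
    graph = _graph_from_faces(faces, nv)
    # hemispheres are the connected components; label by mean x coordinate
    import networkx as nx

    comps = sorted(nx.connected_components(graph),
                   key=lambda c: coords[sorted(c), 0].mean())
    hemisphere = np.zeros(nv, dtype=int)
    for label, comp in enumerate(comps[:2]):
        hemisphere[sorted(comp)] = label
    return ToyMesh(coords, faces, graph, hemisphere)


def write_vertex_stats(stat_map, path) -> None:
    stat_map.table.to_csv(path, sep="\t", index=False)
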