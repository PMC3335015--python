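"""Synthetic case-control cohort generator for the developmental analyses.

Generates phenotype tables, volumetric measure tables and vertexwise
cortical-thickness matrices with the statistical structure the downstream
analyses assume, so the whole pipeline is testable without access to any
MRI data.

The design has four cells: diagnosis (control / ADHD) crossed with an IQ
subgroup (below / above the sample median).  Cell IQ distributions and
per-measure cell means and SDs default to values typical of a pediatric
case-control morphometry sample of ~200 children (ages 6-15, IQ >= 70).
Three cross-measure associations are engineered explicitly:

* within controls, IQ correlates positively with cerebral gray matter
  volume (r = .31) and with mean cerebral white-matter FA (r = .38);
* within ADHD, those correlations are absent, while IQ correlates
  negatively with mean cortical thickness (r = -.25).

Because the cells already differ in both IQ and measure means, part of a
pooled within-diagnosis correlation is carried by the between-cell mean
structure.  The generator therefore solves for the within-cell correlation
that makes the *pooled* within-diagnosis correlation hit its target.

Thickness maps follow a peaked developmental trajectory

    thickness(age) = baseline + amplitude * exp(-(age - peak)^2 / (2 width^2))
                     - decline_slope * max(0, age - peak)

shared by all four cells, except that ADHD subjects below the median IQ have
the peak age shifted later at a designated vertex cluster (delayed
maturation) and ADHD subjects above the median IQ have the whole curve
lowered by a fixed offset (thinner but developmentally parallel cortex).
Vertex noise is spatially smoothed on the mesh with a graph FWHM kernel and
rescaled so every vertex keeps the nominal residual SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidArgumentError
from .mesh import (
    ToyMesh,
    build_toy_mesh,
    default_affected_cluster,
    smoothing_matrix,
)
from .volumetrics import median_split

CELLS = (
    ("control", "below"),
    ("control", "above"),
    ("ADHD", "below"),
    ("ADHD", "above"),
)

#: per-cell IQ mean/SD defaults (scale points).  By default both cells of a
#: diagnosis share the group-level distribution (control 106.0/12.9, ADHD
#: 101.6/16.0): IQ subgroups are formed downstream by the realized median
#: split, exactly as in the analysis, and the realized subgroup moments then
#: approximate the usual below/above-median cell values on their own.
#: Distinct per-cell distributions remain configurable.
DEFAULT_IQ_CELLS = {
    ("control", "below"): (106.0, 12.9),
    ("control", "above"): (106.0, 12.9),
    ("ADHD", "below"): (101.6, 16.0),
    ("ADHD", "above"): (101.6, 16.0),
}

#: per-measure per-cell (mean, sd) defaults; volumes in ml, thickness in mm,
#: surface area in cm^2, FA dimensionless.
DEFAULT_VOLUMETRIC_TARGETS = {
    "intracranial_volume": {
        ("control", "below"): (1508.6, 127.1), ("control", "above"): (1570.2, 133.0),
        ("ADHD", "below"): (1478.1, 123.1), ("ADHD", "above"): (1508.4, 121.4),
    },
    "total_brain": {
        ("control", "below"): (1366.4, 111.6), ("control", "above"): (1411.1, 118.3),
        ("ADHD", "below"): (1335.4, 114.8), ("ADHD", "above"): (1360.7, 111.3),
    },
    "total_cerebrum": {
        ("control", "below"): (1217.1, 99.7), ("control", "above"): (1259.2, 112.0),
        ("ADHD", "below"): (1189.1, 108.3), ("ADHD", "above"): (1210.8, 102.8),
    },
    "total_cerebellum": {
        ("control", "below"): (152.0, 14.0), ("control", "above"): (160.5, 15.8),
        ("ADHD", "below"): (148.4, 12.7), ("ADHD", "above"): (154.7, 11.3),
    },
    "lateral_ventricles": {
        ("control", "below"): (9.9, 5.9), ("control", "above"): (9.2, 5.2),
        ("ADHD", "below"): (9.2, 5.5), ("ADHD", "above"): (9.0, 6.0),
    },
    "third_ventricle": {
        ("control", "below"): (0.55, 0.30), ("control", "above"): (0.56, 0.24),
        ("ADHD", "below"): (0.53, 0.26), ("ADHD", "above"): (0.56, 0.35),
    },
    "cerebral_gray_matter": {
        ("control", "below"): (714.8, 59.7), ("control", "above"): (748.6, 67.0),
        ("ADHD", "below"): (697.7, 62.5), ("ADHD", "above"): (704.3, 63.5),
    },
    "cerebral_white_matter": {
        ("control", "below"): (484.2, 55.8), ("control", "above"): (491.8, 58.0),
        ("ADHD", "below"): (474.9, 59.8), ("ADHD", "above"): (487.8, 55.9),
    },
    "cerebellar_gray_matter": {
        ("control", "below"): (106.3, 11.0), ("control", "above"): (111.5, 10.4),
        ("ADHD", "below"): (102.7, 9.4), ("ADHD", "above"): (107.2, 9.2),
    },
    "cerebellar_white_matter": {
        ("control", "below"): (45.3, 7.8), ("control", "above"): (47.9, 8.4),
        ("ADHD", "below"): (44.2, 6.6), ("ADHD", "above"): (46.6, 8.3),
    },
    "mean_cortical_thickness": {
        ("control", "below"): (3.338, 0.106), ("control", "above"): (3.348, 0.097),
        ("ADHD", "below"): (3.372, 0.102), ("ADHD", "above"): (3.306, 0.109),
    },
    "cortical_surface_area": {
        ("control", "below"): (1876.3, 145.6), ("control", "above"): (1926.2, 159.9),
        ("ADHD", "below"): (1823.3, 151.8), ("ADHD", "above"): (1864.2, 166.5),
    },
    # FA is a per-subject scalar without an IQ-subgroup split; both cells of a
    # diagnosis share the group-level target.
    "cerebral_fa": {
        ("control", "below"): (0.379, 0.023), ("control", "above"): (0.379, 0.023),
        ("ADHD", "below"): (0.374, 0.020), ("ADHD", "above"): (0.374, 0.020),
    },
}

#: measures drawn from a right-skewed (moment-matched log-normal) law
SKEWED_MEASURES = ("lateral_ventricles", "third_ventricle")

#: measures whose pooled within-diagnosis correlation with IQ is pinned
#: (diagnosis, measure) -> config key in target_correlations
_PINNED = {
    ("control", "cerebral_gray_matter"): "control_gm_iq",
    ("ADHD", "cerebral_gray_matter"): "adhd_gm_iq",
    ("control", "cerebral_fa"): "control_fa_iq",
    ("ADHD", "cerebral_fa"): "adhd_fa_iq",
    ("ADHD", "mean_cortical_thickness"): "adhd_thickness_iq",
}

#: sex / handedness marginals, identical across cells (fractions of subjects)
SEX_P_FEMALE = 0.14
HAND_PROBS = {"R": 0.84, "L": 0.13, "A": 0.03}
#: fraction scanned with the thinner-slice (later) protocol
SLICE_P_LATER = 0.315
#: fraction of ADHD subjects with an established medication history
MEDICATION_P_KNOWN = 0.83
#: mean/SD of the corrected medication-duration fraction
MEDICATION_FRACTION = (0.39, 0.25)


@dataclass(frozen=True)
class TrajectoryGenModel:
    """Generative parameters of the thickness-by-age trajectory.

    Units: mm for thickness quantities, years for ages.  With
    ``peak_shift_y = 0`` and ``intercept_offset_mm = 0`` all four design
    cells share a single expected curve.
    """

    baseline_mm: float = 3.36
    amplitude_mm: float = 0.25
    peak_age_y: float = 7.5
    width_y: float = 2.0
    decline_slope_mm_per_y: float = 0.04
    peak_shift_y: float = 1.5
    intercept_offset_mm: float = 0.05
    noise_sd_mm: float = 0.1
    affected_vertices: np.ndarray | None = None  #: default: 30-vertex cluster

    def __post_init__(self):
        if self.width_y <= 0:
            raise ConfigurationError("width_y must be positive")
        if self.noise_sd_mm < 0:
            raise ConfigurationError("noise_sd_mm must be non-negative")

    def curve(self, ages, shifted: bool = False) -> np.ndarray:
        """Expected thickness at the given ages (optionally peak-shifted)."""
        a = np.asarray(ages, dtype=float)
        peak = self.peak_age_y + (self.peak_shift_y if shifted else 0.0)
        bump = self.amplitude_mm * np.exp(-((a - peak) ** 2) / (2 * self.width_y**2))
        decline = self.decline_slope_mm_per_y * np.maximum(0.0, a - peak)
        return self.baseline_mm + bump - decline


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one synthetic cohort."""

    n_per_cell: int = 50
    age_range: tuple[float, float] = (6.0, 15.0)
    iq_means_sds: dict = field(default_factory=lambda: dict(DEFAULT_IQ_CELLS))
    volumetric_targets: dict = field(
        default_factory=lambda: {
            m: dict(cells) for m, cells in DEFAULT_VOLUMETRIC_TARGETS.items()
        }
    )
    target_correlations: dict = field(
        default_factory=lambda: {
            "control_gm_iq": 0.31,
            "control_fa_iq": 0.38,
            "adhd_gm_iq": 0.0,
            "adhd_fa_iq": 0.0,
            "adhd_thickness_iq": -0.25,
        }
    )
    seed: int = 0
    n_vertices: int = 250  #: per hemisphere
    fwhm: float = 2.0  #: graph-edge units
    trajectory: TrajectoryGenModel = field(default_factory=TrajectoryGenModel)

    def __post_init__(self):
        if self.n_per_cell < 3:
            raise ConfigurationError("n_per_cell must be at least 3")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range lower bound must be below upper")
        for cell, (_, sd) in self.iq_means_sds.items():
            if sd < 0:
                raise ConfigurationError(f"negative IQ SD for cell {cell}")
        known = set(DEFAULT_VOLUMETRIC_TARGETS)
        unknown = set(self.volumetric_targets) - known
        if unknown:
            raise ConfigurationError(f"unknown measures in targets: {sorted(unknown)}")
        for measure, cells in self.volumetric_targets.items():
            for cell, (_, sd) in cells.items():
                if sd < 0:
                    raise ConfigurationError(f"negative SD for {measure} {cell}")
        for name, r in self.target_correlations.items():
            if not abs(r) < 1:
                raise ConfigurationError(f"|r| must be < 1 for {name}")
        if self.fwhm < 0:
            raise ConfigurationError("fwhm must be non-negative")


def _truncated_normal(rng, mean, sd, lower, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate the phenotype table: four cells of ``n_per_cell`` subjects.

    Ages are uniform on ``age_range`` with the same law in every cell
    (cells are age-matched by construction); IQ is drawn from the cell's
    normal distribution truncated at 70 (the inclusion floor); sex,
    handedness and the scanner slice dummy share one marginal across cells.
    Output columns: id, diagnosis, age, sex, hand, iq, slice_dummy,
    med_months.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    rows = []
    counter = 1
    for diagnosis, iq_group in CELLS:
        mean, sd = config.iq_means_sds[(diagnosis, iq_group)]
        n = config.n_per_cell
        ages = rng.uniform(lo, hi, n)
        iq = _truncated_normal(rng, mean, sd, 70.0, n)
        sex = np.where(rng.random(n) < SEX_P_FEMALE, "F", "M")
        hand = rng.choice(
            list(HAND_PROBS), size=n, p=list(HAND_PROBS.values())
        )
        slice_dummy = (rng.random(n) < SLICE_P_LATER).astype(int)
        if diagnosis == "ADHD":
            known = rng.random(n) < MEDICATION_P_KNOWN
            frac = _truncated_normal(rng, *MEDICATION_FRACTION, 0.0, n)
            frac = np.minimum(frac, 1.0)
            months = frac * (ages * 12.0 - 60.0)
            med = np.where(known, np.round(months, 1), np.nan)
        else:
            med = np.full(n, np.nan)
        for i in range(n):
            rows.append(
                {
                    "id": f"s{counter:04d}",
                    "diagnosis": diagnosis,
                    "age": float(ages[i]),
                    "sex": str(sex[i]),
                    "hand": str(hand[i]),
                    "iq": float(iq[i]),
                    "slice_dummy": int(slice_dummy[i]),
                    "med_months": float(med[i]),
                }
            )
            counter += 1
    return pd.DataFrame(rows)


def _pooled_moments(cells):
    """Pooled mean/SD from equally weighted cell (mean, sd) pairs."""
    means = np.array([m for m, _ in cells])
    sds = np.array([s for _, s in cells])
    mean = means.mean()
    var = (sds**2).mean() + ((means - mean) ** 2).mean()
    return mean, np.sqrt(var)


def _within_cell_r(target_r, iq_cells, measure_cells):
    """Within-cell correlation needed to hit a pooled within-group target.

    A pooled covariance decomposes into the average within-cell covariance
    plus the covariance of the cell means; given the configured cell means
    and SDs, the within-cell correlation is whatever is left over after the
    between-cell term.
    """
    iq_mean, iq_sd = _pooled_moments(iq_cells)
    m_mean, m_sd = _pooled_moments(measure_cells)
    between = np.mean(
        [
            (im - iq_mean) * (mm - m_mean)
            for (im, _), (mm, _) in zip(iq_cells, measure_cells)
        ]
    )
    within_scale = np.mean(
        [isd * msd for (_, isd), (_, msd) in zip(iq_cells, measure_cells)]
    )
    needed = target_r * iq_sd * m_sd - between
    if within_scale <= 0:
        return 0.0
    return float(np.clip(needed / within_scale, -0.99, 0.99))


def generate_volumetrics(phenotypes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate the per-subject volumetric measure table.

    Each measure is drawn cell by cell so that cell means and SDs match the
    configured targets in expectation.  Measures with a pinned IQ
    correlation are built as ``mean + sd * (r_w z_iq + sqrt(1-r_w^2) eps)``
    where ``z_iq`` standardizes IQ within the cell and ``r_w`` is solved so
    the pooled within-diagnosis correlation hits the configured target.
    Ventricle volumes come from a moment-matched log-normal (right-skewed)
    law.  Rows align with ``phenotypes``.
    """
    if len(phenotypes) == 0:
        raise InvalidArgumentError("phenotype table is empty")
    rng = np.random.default_rng(config.seed + 1)
    iq_groups, _ = median_split(phenotypes)
    out = pd.DataFrame({"id": phenotypes["id"].to_numpy()}, index=phenotypes.index)

    for measure, targets in config.volumetric_targets.items():
        values = np.empty(len(phenotypes))
        # resolve the within-cell r per diagnosis group
        r_within = {}
        for diagnosis in ("control", "ADHD"):
            key = _PINNED.get((diagnosis, measure))
            if key is None or key not in config.target_correlations:
                r_within[diagnosis] = None  # unconstrained: independent noise
                continue
            cells = [(diagnosis, "below"), (diagnosis, "above")]
            iq_cells = []
            m_cells = []
            for cell in cells:
                mask = (phenotypes["diagnosis"] == cell[0]) & (iq_groups == cell[1])
                iq = phenotypes.loc[mask, "iq"].to_numpy(dtype=float)
                if iq.size >= 2 and iq.std(ddof=0) > 0:
                    iq_cells.append((iq.mean(), iq.std(ddof=0)))
                else:
                    iq_cells.append(config.iq_means_sds[cell])
                m_cells.append(targets[cell])
            r_within[diagnosis] = _within_cell_r(
                config.target_correlations[key], iq_cells, m_cells
            )
        for diagnosis, iq_group in CELLS:
            mask = ((phenotypes["diagnosis"] == diagnosis)
                    & (iq_groups == iq_group)).to_numpy()
            n = int(mask.sum())
            if n == 0:
                continue
            mean, sd = targets[(diagnosis, iq_group)]
            if measure in SKEWED_MEASURES:
                if sd == 0:
                    values[mask] = mean
                else:
                    s2 = np.log1p((sd / mean) ** 2)
                    mu = np.log(mean) - s2 / 2.0
                    values[mask] = rng.lognormal(mu, np.sqrt(s2), n)
                continue
            eps = rng.standard_normal(n)
            r_w = r_within[diagnosis]
            if r_w is None or sd == 0:
                values[mask] = mean + sd * eps
            else:
                iq = phenotypes.loc[mask, "iq"].to_numpy(dtype=float)
                iq_sd = iq.std(ddof=0)
                z = (iq - iq.mean()) / iq_sd if iq_sd > 0 else np.zeros(n)
                values[mask] = mean + sd * (
                    r_w * z + np.sqrt(1.0 - r_w**2) * eps
                )
        out[measure] = values
    return out


def generate_thickness_maps(
    phenotypes: pd.DataFrame,
    mesh: ToyMesh,
    model: TrajectoryGenModel,
    config: SimConfig,
) -> pd.DataFrame:
    """Generate the subjects x vertices cortical-thickness matrix.

    Every subject's row is the cell-specific trajectory evaluated at their
    age — peak-shifted at the affected vertex cluster for ADHD subjects
    below the median IQ, and lowered uniformly by the intercept offset for
    ADHD subjects above it — plus spatially smoothed Gaussian vertex noise
    rescaled so each vertex keeps residual SD ``noise_sd_mm``.
    """
    affected = model.affected_vertices
    if affected is None:
        affected = default_affected_cluster(mesh)
    affected = np.asarray(affected, dtype=int)
    if affected.size and (affected.min() < 0 or affected.max() >= mesh.n_vertices):
        raise InvalidArgumentError("affected_vertices outside the mesh")
    if affected.size == 0 and model.peak_shift_y != 0:
        warnings.warn("peak_shift_y is nonzero but no vertices are affected")

    rng = np.random.default_rng(config.seed + 2)
    iq_groups, _ = median_split(phenotypes)
    ages = phenotypes["age"].to_numpy(dtype=float)
    V = mesh.n_vertices
    n = len(phenotypes)

    base = model.curve(ages)  # (n,)
    thickness = np.tile(base[:, None], (1, V))
    is_adhd = (phenotypes["diagnosis"] == "ADHD").to_numpy()
    below = (iq_groups == "below").to_numpy()
    shifted_rows = is_adhd & below
    if affected.size and shifted_rows.any():
        shifted = model.curve(ages[shifted_rows], shifted=True)
        thickness[np.ix_(shifted_rows, affected)] = shifted[:, None]
    offset_rows = is_adhd & ~below
    thickness[offset_rows, :] -= model.intercept_offset_mm

    if model.noise_sd_mm > 0:
        eps = rng.normal(0.0, model.noise_sd_mm, size=(n, V))
        S = smoothing_matrix(mesh, config.fwhm)
        # smoothing shrinks pointwise variance; rescale per vertex so the
        # marginal SD stays at noise_sd_mm while correlations are kept
        norm = np.sqrt((S**2).sum(axis=1))
        thickness += (eps @ S.T) / norm[None, :]

    cols = [f"v{j}" for j in range(V)]
    return pd.DataFrame(thickness, index=phenotypes.index, columns=cols)


def simulate_all(config: SimConfig):
    """Convenience wrapper: mesh, phenotypes, volumetrics and thickness maps."""
    mesh = build_toy_mesh(config.n_vertices, config.seed + 3)
    model = config.trajectory
    if model.affected_vertices is None:
        model = replace(model, affected_vertices=default_affected_cluster(mesh))
    phenotypes = generate_cohort(config)
    volumes = generate_volumetrics(phenotypes, config)
    thickness = generate_thickness_maps(phenotypes, mesh, model, config)
    return mesh, phenotypes, volumes, thickness
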