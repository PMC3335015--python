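"""Per-vertex comparison of developmental trajectories between groups.

At each vertex the thickness-by-age relationship is fitted three times with
the running-line smoother and parsimony df selection: once for the pooled
sample (the null: one shared curve) and once per diagnostic group (the
alternative: two curves).  The F comparison of one curve versus two is then
run at a common flexibility — the pooled walk's chosen df, raised when both
group walks independently selected something wigglier — so that the null
and alternative form a single nested family:

    F = [(RSS_pooled - RSS_g1 - RSS_g2) / ddf] / [(RSS_g1 + RSS_g2) / (n - df_g1 - df_g2)]

with ddf = df_g1 + df_g2 - df_pooled (all fits at the common df).  Comparing
fits of unequal flexibility instead conflates selection noise with group
differences: a chance overfit in one group, or shared curvature the pooled
walk missed, inflates the statistic's null tail and breaks FDR control.  A
signed companion statistic, sign(mean fitted group difference over an age
grid) * sqrt(F), plays the role of a t-map.  Vertex p-values are corrected
across the whole surface with the Benjamini-Hochberg step-up rule.

Trajectory fits are restricted to subjects below an age cutoff (default 14
years) because running-line fits are unstable where the age distribution
thins out.  Thickness is by default residualized on sex, handedness and the
scanner slice dummy before fitting.

The module exposes both a scalar, per-vertex API (``trajectory_difference_test``)
and a vectorized whole-surface driver (``vertexwise_analysis``) that computes
identical numbers by sharing smoother operators across vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .smoother import (
    default_ladder,
    fit_trajectory,
    select_df,
    smoother_matrix,
    span_for_df,
)

GRID_POINTS = 50


@dataclass(frozen=True)
class AnalysisWindow:
    """Age window and minimum group size for trajectory analyses."""

    max_age_y: float = 14.0
    min_group_n: int = 5

    def __post_init__(self):
        if self.min_group_n < 5:
            raise InvalidArgumentError("min_group_n must be at least 5")


@dataclass
class VertexStatMap:
    """Vertexwise trajectory-difference statistics with FDR control.

    ``table`` has one row per vertex: F, signed_stat, p, q, rejected, and
    the chosen df for each group and the pooled fit.  ``critical_stats``
    maps hemisphere label to the smallest |signed statistic| among rejected
    vertices (NaN when the hemisphere has no rejections) — the realized
    significance threshold on the statistic scale.
    """

    table: pd.DataFrame
    fdr_level: float
    critical_stats: dict
    summary: dict = field(default_factory=dict)


def age_filter(phenotypes: pd.DataFrame, window: AnalysisWindow) -> pd.DataFrame:
    """Retain subjects strictly below the age cutoff.

    Raises :class:`InsufficientDataError` naming the group if any diagnostic
    group drops below ``min_group_n``.
    """
    kept = phenotypes.loc[phenotypes["age"] < window.max_age_y].copy()
    for group, sub in kept.groupby("diagnosis"):
        if len(sub) < window.min_group_n:
            raise InsufficientDataError(
                f"group {group!r} has {len(sub)} subjects below age "
                f"{window.max_age_y}; need at least {window.min_group_n}"
            )
    if kept["diagnosis"].nunique() < phenotypes["diagnosis"].nunique():
        lost = set(phenotypes["diagnosis"]) - set(kept["diagnosis"])
        raise InsufficientDataError(f"group {lost} empty after age filtering")
    return kept


def bh_fdr(p_values, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR over a family of p-values.

    Returns (q_values, rejected) in the input order.  q_(i) is the smallest
    level at which the i-th smallest p would still be rejected:
    min over j >= i of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    thresh = ranked <= np.arange(1, m + 1) * level / m
    rejected_sorted = np.zeros(m, dtype=bool)
    if thresh.any():
        k = np.max(np.flatnonzero(thresh))
        rejected_sorted[: k + 1] = True
    q = np.empty(m)
    rejected = np.empty(m, dtype=bool)
    q[order] = q_sorted
    rejected[order] = rejected_sorted
    return q, rejected


def _difference_from_fits(fit_pooled, fit_1, fit_2, grid, covariate_df=0) -> dict:
    """F, p and signed statistic from the three fitted curves.

    The caller must guarantee nesting: the pooled (one-curve) fit has to be
    at least as flexible as each group fit, otherwise shared curvature the
    pooled model cannot express masquerades as a group difference.
    ``covariate_df`` charges the residual degrees of freedom for nuisance
    parameters removed from the data before fitting (residualization).
    """
    n = fit_pooled.n
    df1, df2, dfp = fit_1.effective_df, fit_2.effective_df, fit_pooled.effective_df
    ddf = df1 + df2 - dfp
    resid_df = n - df1 - df2 - covariate_df
    if ddf <= 1e-9 or resid_df <= 0:
        return {
            "F": 0.0, "p": 1.0, "signed_stat": 0.0, "degenerate": True,
            "df_g1": df1, "df_g2": df2, "df_pooled": dfp,
        }
    rss_sep = fit_1.rss + fit_2.rss
    floor = 1e-12 * fit_pooled.tss
    num = (fit_pooled.rss - rss_sep) / ddf
    if fit_pooled.rss <= floor:
        num = 0.0
    if num <= 0 or rss_sep <= floor:
        F, p = (0.0, 1.0) if num <= 0 else (float("inf"), 0.0)
    else:
        F = num / (rss_sep / resid_df)
        p = float(stats.f.sf(F, ddf, resid_df))
    diff = fit_2.predict(grid) - fit_1.predict(grid)
    mean_diff = float(np.mean(diff))
    sign = 0.0 if mean_diff == 0 else float(np.sign(mean_diff))
    return {
        "F": float(F), "p": p, "signed_stat": sign * float(np.sqrt(F)),
        "degenerate": False, "df_g1": df1, "df_g2": df2, "df_pooled": dfp,
    }


def trajectory_difference_test(
    ages, y, group_labels, ladder=None, alpha: float = 0.05,
    group_order=None, covariate_df: int = 0,
) -> dict:
    """Pooled-versus-separate trajectory comparison for one vertex/measure.

    The pooled sample and each group get their own parsimony df selection;
    the signed statistic is sign(mean fitted difference of the second group
    minus the first over a 50-point age grid) * sqrt(F).  ``group_order``
    fixes which group is subtracted from which (default: sorted labels,
    so ('ADHD', 'control') sorts ADHD first; pass ('control', 'ADHD') for an
    ADHD-minus-control sign).
    """
    a = np.asarray(ages, dtype=float)
    v = np.asarray(y, dtype=float)
    labels = np.asarray(group_labels)
    if not (a.shape == v.shape == labels.shape):
        raise InvalidArgumentError("ages, y and group_labels must align")
    uniq = sorted(np.unique(labels).tolist()) if group_order is None else list(group_order)
    if len(uniq) != 2 or set(uniq) != set(np.unique(labels)):
        raise InvalidArgumentError("exactly two groups are required")
    sel_pooled = select_df(a, v, ladder, alpha)
    m1 = labels == uniq[0]
    m2 = labels == uniq[1]
    sel_1 = select_df(a[m1], v[m1], ladder, alpha)
    sel_2 = select_df(a[m2], v[m2], ladder, alpha)
    # The F comparison is run at a common flexibility, so one curve versus
    # two is tested within a single nested family.  The common df is the
    # pooled walk's choice, raised when both groups independently selected
    # something wigglier (shape effects that cancel in the pool); flexibility
    # claimed by a single group alone is ignored because a chance overfit in
    # one group would otherwise masquerade as a group difference.
    common_df = max(sel_pooled.chosen_df,
                    min(sel_1.chosen_df, sel_2.chosen_df))

    def at_common(sel, ages_g, y_g):
        if sel.chosen_df == common_df:
            return sel.fit
        return fit_trajectory(ages_g, y_g, common_df)

    fit_pooled = at_common(sel_pooled, a, v)
    fit_1 = at_common(sel_1, a[m1], v[m1])
    fit_2 = at_common(sel_2, a[m2], v[m2])
    grid = np.linspace(a.min(), a.max(), GRID_POINTS)
    out = _difference_from_fits(fit_pooled, fit_1, fit_2, grid,
                                covariate_df=covariate_df)
    out["df_selected"] = {
        "pooled": sel_pooled.chosen_df,
        uniq[0]: sel_1.chosen_df,
        uniq[1]: sel_2.chosen_df,
    }
    out["df_common"] = common_df
    return out


class _LadderEngine:
    """Shared-operator engine: fits all vertices at every ladder df at once.

    For a fixed age vector the smoother operator at each ladder df is a
    single matrix, so fitted values for all vertices are one matmul.  The
    per-vertex parsimony walk is then evaluated on the precomputed RSS
    ladder, reproducing the scalar ``select_df`` decisions exactly.
    """

    def __init__(self, ages: np.ndarray, ladder: list[float]):
        self.ages = np.asarray(ages, dtype=float)
        self.n = self.ages.size
        self.ladder = ladder
        self._ops: dict[int, np.ndarray | None] = {}
        self._edf: dict[int, float] = {}
        self._grid_ops: dict[int, np.ndarray] = {}

    def _operator(self, idx: int):
        if idx not in self._ops:
            df = self.ladder[idx]
            if df == 1.0:
                S = np.full((self.n, self.n), 1.0 / self.n)
                edf = 1.0
            elif df == 2.0:
                x = self.ages
                xc = x - x.mean()
                sxx = (xc**2).sum()
                S = 1.0 / self.n + np.outer(xc, xc) / sxx
                edf = 2.0
            else:
                sr = span_for_df(self.ages, df)
                S = smoother_matrix(self.ages, sr.span)
                edf = sr.achieved_df
            self._ops[idx] = S
            self._edf[idx] = edf
        return self._ops[idx], self._edf[idx]

    def grid_operator(self, idx: int, grid: np.ndarray) -> np.ndarray:
        if idx not in self._grid_ops:
            df = self.ladder[idx]
            if df == 1.0:
                G = np.full((grid.size, self.n), 1.0 / self.n)
            elif df == 2.0:
                x = self.ages
                xc = x - x.mean()
                sxx = (xc**2).sum()
                G = 1.0 / self.n + np.outer(grid - x.mean(), xc) / sxx
            else:
                sr = span_for_df(self.ages, df)
                G = smoother_matrix(self.ages, sr.span, eval_points=grid)
            self._grid_ops[idx] = G
        return self._grid_ops[idx]

    def rss_ladder(self, Y: np.ndarray):
        """Lazy per-ladder-df RSS table for every column of Y."""
        cache = {}

        def rss_at(idx):
            if idx not in cache:
                S, _ = self._operator(idx)
                R = Y - S @ Y
                cache[idx] = (R**2).sum(axis=0)
            return cache[idx]

        return rss_at

    def select(self, Y: np.ndarray, alpha: float):
        """Vectorized parsimony walk for every column of Y.

        Returns (chosen_idx, rss_at) where ``rss_at`` maps a ladder index to
        the per-column RSS at that df (lazily computed, cached).
        """
        n, V = Y.shape
        rss_at = self.rss_ladder(Y)
        # residuals at machine noise cannot be improved upon
        floor = 1e-12 * ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        chosen = np.zeros(V, dtype=int)
        alive = np.ones(V, dtype=bool)
        for step in range(1, len(self.ladder)):
            if not alive.any():
                break
            _, edf_small = self._operator(step - 1)
            _, edf_big = self._operator(step)
            resid_df = n - edf_big
            if resid_df <= 0:
                break
            rss_s = rss_at(step - 1)
            rss_b = rss_at(step)
            ddf = edf_big - edf_small
            num = (rss_s - rss_b) / ddf
            with np.errstate(divide="ignore", invalid="ignore"):
                F = num / (rss_b / resid_df)
            p = np.where(
                (num <= 0) | (rss_b <= floor) | (rss_s <= floor),
                np.where((num > 0) & (rss_b <= floor) & (rss_s > floor), 0.0, 1.0),
                stats.f.sf(np.maximum(F, 0.0), ddf, resid_df),
            )
            reject = alive & (p < alpha)
            chosen[reject] = step
            alive = reject
        return chosen, rss_at

    def gather(self, idx_array, rss_at):
        """Per-column RSS and effective df at the given ladder indices."""
        V = idx_array.size
        rss = np.empty(V)
        edf = np.empty(V)
        for idx in np.unique(idx_array):
            m = idx_array == idx
            rss[m] = rss_at(int(idx))[m]
            edf[m] = self._operator(int(idx))[1]
        return rss, edf

    def grid_fits(self, Y, chosen_idx, grid):
        """Fitted curves on the age grid at each column's chosen df."""
        out = np.empty((grid.size, Y.shape[1]))
        for idx in np.unique(chosen_idx):
            m = chosen_idx == idx
            G = self.grid_operator(int(idx), grid)
            out[:, m] = G @ Y[:, m]
        return out


def _residualize(Y: np.ndarray, phenotypes: pd.DataFrame) -> np.ndarray:
    """Remove sex / handedness / slice-thickness effects from thickness maps."""
    X = np.column_stack(
        [
            np.ones(len(phenotypes)),
            (phenotypes["sex"] == "F").to_numpy(dtype=float),
            (phenotypes["hand"] == "L").to_numpy(dtype=float),
            (phenotypes["hand"] == "A").to_numpy(dtype=float),
            phenotypes["slice_dummy"].to_numpy(dtype=float),
        ]
    )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid + Y.mean(axis=0, keepdims=True)


def vertexwise_analysis(
    thickness,
    phenotypes: pd.DataFrame,
    mesh=None,
    window: AnalysisWindow | None = None,
    ladder=None,
    alpha: float = 0.05,
    fdr_level: float = 0.05,
    residualize: bool = True,
    group_order=("control", "ADHD"),
    per_hemisphere_fdr: bool = False,
    uncorrected_threshold: float | None = None,
) -> VertexStatMap:
    """Whole-surface trajectory-difference analysis with FDR control.

    Applies the age window, optionally residualizes thickness on nuisance
    covariates, runs the pooled-versus-separate trajectory F test at every
    vertex and corrects the vertex p-values with Benjamini-Hochberg (jointly
    across hemispheres by default, which is the conservative choice; set
    ``per_hemisphere_fdr`` for within-hemisphere control).  The signed
    statistic is oriented as second group minus first of ``group_order``
    (ADHD minus control by default).

    ``uncorrected_threshold`` optionally adds an exploratory boolean column
    flagging vertices below a raw p threshold; it never affects ``rejected``.
    """
    if window is None:
        window = AnalysisWindow()
    if ladder is None:
        ladder = default_ladder()
    ladder = [float(d) for d in ladder]

    Y_full = (
        thickness.to_numpy(dtype=float)
        if isinstance(thickness, pd.DataFrame)
        else np.asarray(thickness, dtype=float)
    )
    if Y_full.shape[0] != len(phenotypes):
        raise AlignmentError(
            f"thickness has {Y_full.shape[0]} rows but phenotypes has "
            f"{len(phenotypes)}"
        )
    if mesh is not None and Y_full.shape[1] != mesh.n_vertices:
        raise AlignmentError("thickness columns do not match mesh vertices")

    pheno = phenotypes.reset_index(drop=True)
    keep_groups = pheno["diagnosis"].isin(group_order).to_numpy()
    pheno = pheno.loc[keep_groups].reset_index(drop=True)
    Y_full = Y_full[keep_groups]
    kept = age_filter(pheno, window)
    rows = kept.index.to_numpy()
    Y = Y_full[rows]
    pheno = kept.reset_index(drop=True)

    if residualize:
        Y = _residualize(Y, pheno)

    ages = pheno["age"].to_numpy(dtype=float)
    labels = pheno["diagnosis"].to_numpy()
    m1 = labels == group_order[0]
    m2 = labels == group_order[1]
    n = ages.size
    V = Y.shape[1]
    grid = np.linspace(ages.min(), ages.max(), GRID_POINTS)

    eng_pooled = _LadderEngine(ages, ladder)
    eng_1 = _LadderEngine(ages[m1], ladder)
    eng_2 = _LadderEngine(ages[m2], ladder)

    idx_p, rss_at_p = eng_pooled.select(Y, alpha)
    idx_1, rss_at_1 = eng_1.select(Y[m1], alpha)
    idx_2, rss_at_2 = eng_2.select(Y[m2], alpha)
    # common flexibility: one curve vs two curves within one nested family
    # (pooled choice, raised when both groups agree on something wigglier)
    idx_common = np.maximum(idx_p, np.minimum(idx_1, idx_2))
    rss_p, edf_p = eng_pooled.gather(idx_common, rss_at_p)
    rss_1, edf_1 = eng_1.gather(idx_common, rss_at_1)
    rss_2, edf_2 = eng_2.gather(idx_common, rss_at_2)

    # residualization consumed nuisance-covariate dimensions; charge them
    n_cov = 4 if residualize else 0
    ddf = edf_1 + edf_2 - edf_p
    resid_df = n - edf_1 - edf_2 - n_cov
    rss_sep = rss_1 + rss_2
    floor = 1e-12 * ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    degenerate = (ddf <= 1e-9) | (resid_df <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (rss_p - rss_sep) / np.where(degenerate, np.nan, ddf)
        F = num / (rss_sep / resid_df)
    F = np.where(degenerate | (num <= 0) | (rss_p <= floor), 0.0, F)
    perfect = (~degenerate) & (num > 0) & (rss_sep <= floor) & (rss_p > floor)
    F = np.where(perfect, np.inf, F)
    p = np.ones(V)
    ok = (~degenerate) & (F > 0) & np.isfinite(F)
    p[ok] = stats.f.sf(F[ok], ddf[ok], resid_df[ok])
    p[perfect] = 0.0

    fit_1 = eng_1.grid_fits(Y[m1], idx_common, grid)
    fit_2 = eng_2.grid_fits(Y[m2], idx_common, grid)
    mean_diff = (fit_2 - fit_1).mean(axis=0)
    sign = np.sign(mean_diff)
    with np.errstate(invalid="ignore"):
        signed = sign * np.sqrt(F)
    signed = np.where(np.isfinite(signed), signed, sign * np.inf)
    signed = np.where(F == 0, 0.0, signed)

    hemi = (
        mesh.hemisphere if mesh is not None else np.zeros(V, dtype=int)
    )
    if per_hemisphere_fdr:
        q = np.empty(V)
        rejected = np.empty(V, dtype=bool)
        for h in np.unique(hemi):
            m = hemi == h
            q[m], rejected[m] = bh_fdr(p[m], fdr_level)
    else:
        q, rejected = bh_fdr(p, fdr_level)

    critical = {}
    for h in np.unique(hemi):
        m = (hemi == h) & rejected
        critical[int(h)] = float(np.abs(signed[m]).min()) if m.any() else float("nan")

    table = pd.DataFrame(
        {
            "vertex": np.arange(V),
            "hemisphere": hemi,
            "F": F,
            "signed_stat": signed,
            "p": p,
            "q": q,
            "rejected": rejected,
            "df_control": np.array(ladder)[idx_1],
            "df_adhd": np.array(ladder)[idx_2],
            "df_pooled": np.array(ladder)[idx_p],
            "df_common": np.array(ladder)[idx_common],
        }
    )
    if uncorrected_threshold is not None:
        table["exploratory"] = p < uncorrected_threshold
    summary = {
        "n_used": int(n),
        "n_per_group": {
            str(group_order[0]): int(m1.sum()),
            str(group_order[1]): int(m2.sum()),
        },
        "n_vertices": int(V),
        "n_rejected": int(rejected.sum()),
        "fdr_level": float(fdr_level),
        "alpha": float(alpha),
        "max_age_y": float(window.max_age_y),
        "ladder": ladder,
        "critical_stats": {str(k): v for k, v in critical.items()},
    }
    return VertexStatMap(table, fdr_level, critical, summary)
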