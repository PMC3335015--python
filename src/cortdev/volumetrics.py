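"""Covariate-adjusted volumetric models and IQ-moderation analyses.

Groups are compared on per-subject scalar brain measures with ordinary
least-squares GLMs adjusting for age, sex, hand preference and a scanner
slice-thickness dummy.  Moderation by IQ is tested two ways: dimensionally
(main effect of IQ plus an IQ x diagnosis interaction added to the base
model) and categorically (a split of the whole sample at its median IQ, with
the median value assigned to the below-median subgroup, followed by subgroup
analyses).  Small derived quantities live here too: the upper-tail 1.5-IQR
IQ outlier rule used before any dimensional-IQ model, per-group Pearson
correlations, percent volume reduction, the thickness x surface-area proxy
for cortical gray matter volume, and the age-corrected stimulant-exposure
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateDesignError,
    InvalidArgumentError,
)

BASE_COVARIATES = ("age", "sex", "hand", "slice_dummy")

_TERM_ORDER = (
    "intercept",
    "group",
    "age",
    "sex",
    "hand",
    "slice_dummy",
    "group_x_age",
    "iq",
    "iq_x_group",
)

_INTERACTIONS = {"group_x_age": ("group", "age"), "iq_x_group": ("iq", "group")}


@dataclass(frozen=True)
class GlmSpec:
    """Specification of one volumetric GLM.

    ``terms`` come from {intercept, group, age, sex, hand, slice_dummy,
    group_x_age, iq, iq_x_group}; interactions require their main effects.
    ``transform`` is 'none' or 'log' (natural log; requires a strictly
    positive outcome).
    """

    outcome: str
    terms: tuple[str, ...] = (
        "intercept", "group", "age", "sex", "hand", "slice_dummy",
    )
    transform: str = "none"

    def __post_init__(self):
        unknown = set(self.terms) - set(_TERM_ORDER)
        if unknown:
            raise InvalidArgumentError(f"unknown model terms: {sorted(unknown)}")
        for term, mains in _INTERACTIONS.items():
            if term in self.terms and not all(m in self.terms for m in mains):
                raise InvalidArgumentError(
                    f"interaction {term} requires main effects {mains}"
                )
        if self.transform not in ("none", "log"):
            raise InvalidArgumentError("transform must be 'none' or 'log'")


@dataclass
class GlmResult:
    """Fitted GLM: coefficients, per-term p-values and adjusted group means."""

    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_used: int
    adjusted_means: dict
    transform: str
    adjusted_means_response: dict = field(default_factory=dict)

    def p(self, term: str) -> float:
        return float(self.pvalues[term])


def _design_columns(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Numeric design matrix with treatment coding.

    Reference levels: control, male, right-handed, slice_dummy = 0.
    """
    cols = {}
    for term in terms:
        if term == "intercept":
            cols["intercept"] = np.ones(len(data))
        elif term == "group":
            cols["group"] = (data["diagnosis"] == "ADHD").astype(float).to_numpy()
        elif term == "sex":
            cols["sex"] = (data["sex"] == "F").astype(float).to_numpy()
        elif term == "hand":
            cols["hand_L"] = (data["hand"] == "L").astype(float).to_numpy()
            cols["hand_A"] = (data["hand"] == "A").astype(float).to_numpy()
        elif term in ("age", "iq", "slice_dummy"):
            cols[term] = data[term].astype(float).to_numpy()
        elif term == "group_x_age":
            cols["group_x_age"] = (
                (data["diagnosis"] == "ADHD").astype(float) * data["age"]
            ).to_numpy()
        elif term == "iq_x_group":
            cols["iq_x_group"] = (
                (data["diagnosis"] == "ADHD").astype(float) * data["iq"]
            ).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def fit_glm(data: pd.DataFrame, spec: GlmSpec) -> GlmResult:
    """Ordinary least-squares fit of a volumetric GLM.

    Rows with missing values in the outcome or any model column are dropped
    (listwise deletion).  Adjusted group means are the model predictions at
    the sample means of every covariate, with the group indicator set to 0
    (control) or 1 (ADHD); for log outcomes an exponentiated companion is
    reported as well.
    """
    needed = {spec.outcome}
    for term in spec.terms:
        if term == "group":
            needed.add("diagnosis")
        elif term == "group_x_age":
            needed.update(("diagnosis", "age"))
        elif term == "iq_x_group":
            needed.update(("diagnosis", "iq"))
        elif term != "intercept":
            needed.add(term)
    missing_cols = needed - set(data.columns)
    if missing_cols:
        raise InvalidArgumentError(f"missing columns: {sorted(missing_cols)}")
    used = data.dropna(subset=sorted(needed))
    if len(used) < len(spec.terms) + 2:
        raise DegenerateDesignError("too few complete rows for this model")

    y = used[spec.outcome].astype(float).to_numpy()
    if spec.transform == "log":
        if np.any(y <= 0):
            raise InvalidArgumentError(
                f"log transform requires a strictly positive outcome "
                f"({spec.outcome} has non-positive values)"
            )
        y = np.log(y)

    X = _design_columns(used, spec.terms)
    # dummies for factor levels absent from the data (and other constant
    # nuisance covariates) carry no information: drop them, as a formula
    # interface would only code observed levels
    for col in ("sex", "hand_L", "hand_A", "slice_dummy"):
        if col in X.columns and X[col].nunique() == 1:
            X = X.drop(columns=col)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(X.to_numpy(), mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        aliased += [X.columns[p] for p in piv[len(diag):]]
        raise CollinearityError(f"rank-deficient design; aliased terms: {aliased}")

    res = sm.OLS(y, X).fit()

    # Adjusted group means at covariate means of the rows actually used.
    xbar = X.mean(axis=0)
    adjusted = {}
    for label, g in (("control", 0.0), ("ADHD", 1.0)):
        row = xbar.copy()
        if "group" in row.index:
            row["group"] = g
        if "group_x_age" in row.index:
            row["group_x_age"] = g * used["age"].astype(float).mean()
        if "iq_x_group" in row.index:
            row["iq_x_group"] = g * used["iq"].astype(float).mean()
        adjusted[label] = float(row @ res.params)
    result = GlmResult(
        outcome=spec.outcome,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        n_used=int(len(used)),
        adjusted_means=adjusted,
        transform=spec.transform,
    )
    if spec.transform == "log":
        result.adjusted_means_response = {
            k: float(np.exp(v)) for k, v in adjusted.items()
        }
    return result


def dimensional_iq_model(
    data: pd.DataFrame, outcome: str, transform: str = "none",
    covariates: tuple[str, ...] = BASE_COVARIATES,
) -> GlmResult:
    """Base model plus a main effect of IQ and an IQ x group interaction.

    Callers are expected to have applied :func:`exclude_iq_outliers` first,
    since these models treat IQ as a continuous variable.
    """
    iq = data["iq"].dropna()
    if iq.nunique() <= 1:
        raise DegenerateDesignError("IQ is constant; dimensional model undefined")
    terms = ("intercept", "group", *covariates, "iq", "iq_x_group")
    # 'hand'/'sex' may be absent from reduced covariate sets
    spec = GlmSpec(outcome=outcome, terms=terms, transform=transform)
    return fit_glm(data, spec)


def median_split(phenotypes: pd.DataFrame) -> tuple[pd.Series, float]:
    """Split the whole sample at its median IQ.

    The median is computed over both diagnostic groups together; subjects at
    or below the median are labeled ``below``, strictly above it ``above``
    (the median subject goes to the below-median subgroup).
    """
    iq = phenotypes["iq"]
    if iq.isna().any():
        raise InvalidArgumentError("IQ must be present for all subjects")
    median = float(np.median(iq.to_numpy(dtype=float)))
    labels = pd.Series(
        np.where(iq <= median, "below", "above"), index=phenotypes.index,
        name="iq_group",
    )
    if labels.nunique() < 2:
        raise DegenerateDesignError(
            "median split produced an empty subgroup (IQ nearly constant)"
        )
    return labels, median


def exclude_iq_outliers(phenotypes: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop upper-tail IQ outliers by the 1.5-IQR criterion.

    Only the upper tail is trimmed (very high IQ is sparsely sampled and
    leverages dimensional fits); the filtered table and the excluded subject
    ids are returned.  Meant for analyses treating IQ continuously.
    """
    iq = phenotypes["iq"].to_numpy(dtype=float)
    q1, q3 = np.percentile(iq, [25, 75])
    cutoff = q3 + 1.5 * (q3 - q1)
    keep = phenotypes["iq"] <= cutoff
    excluded = phenotypes.loc[~keep, "id"].tolist() if "id" in phenotypes else (
        phenotypes.index[~keep].tolist()
    )
    return phenotypes.loc[keep].copy(), excluded


def group_correlation(
    data: pd.DataFrame, measure: str, group_col: str = "diagnosis",
    partial: bool = False, covariates: tuple[str, ...] = BASE_COVARIATES,
) -> dict:
    """Pearson correlation between IQ and a measure within each group.

    With ``partial=True`` both variables are first residualized on the
    covariates within group (zero-order correlations are the default, which
    is what raw scatterplots show).
    """
    out = {}
    for group, sub in data.groupby(group_col):
        sub = sub.dropna(subset=["iq", measure])
        if len(sub) < 3:
            raise InvalidArgumentError(f"fewer than 3 subjects in group {group}")
        x = sub["iq"].to_numpy(dtype=float)
        y = sub[measure].to_numpy(dtype=float)
        if partial:
            Z = _design_columns(sub, ("intercept", *covariates)).to_numpy()
            x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
            y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegenerateDesignError(
                f"constant column in group {group}: correlation undefined"
            )
        r, p = stats.pearsonr(x, y)
        out[group] = {"r": float(r), "p": float(p), "n": int(len(sub))}
    return out


def percent_reduction(mean_control: float, mean_adhd: float) -> float:
    """Percent reduction of the ADHD mean relative to the control mean."""
    if mean_control <= 0:
        raise InvalidArgumentError("control mean must be positive")
    return 100.0 * (mean_control - mean_adhd) / mean_control


def cortical_gm_proxy(mean_thickness_mm: float, surface_area_cm2: float) -> float:
    """Cortical gray matter volume proxy: thickness x surface area, in ml.

    mm x cm^2 = 0.1 ml, so the product is scaled by 0.1.
    """
    if mean_thickness_mm <= 0 or surface_area_cm2 <= 0:
        raise InvalidArgumentError("thickness and surface area must be positive")
    return 0.1 * mean_thickness_mm * surface_area_cm2


def corrected_medication_duration(months_used, age_months):
    """Stimulant exposure as a fraction of the prescribable lifetime.

    months_used / (age_months - 60); 60 months is the youngest age at which
    stimulants are prescribed, so younger ages are invalid.  Missing
    months_used propagates as missing.
    """
    months = np.asarray(months_used, dtype=float)
    age = np.asarray(age_months, dtype=float)
    if np.any(age <= 60):
        raise InvalidArgumentError("age_months must exceed 60 months")
    out = months / (age - 60.0)
    return float(out) if out.ndim == 0 else out


#: outcome -> transform for measures needing a log (right-skewed) analysis
LOG_MEASURES = ("lateral_ventricles", "third_ventricle")


def summarize_volumetrics(
    phenotypes: pd.DataFrame, volumes: pd.DataFrame, measures=None,
) -> pd.DataFrame:
    """Per-measure summary table of group and IQ-moderation effects.

    For each measure: raw cell means/SDs (all and per IQ subgroup within
    diagnosis), the covariate-adjusted group p-value overall and within IQ
    subgroups, the group x age interaction p, and the dimensional p_IQ and
    p_IQ x group (computed after upper-tail IQ outlier exclusion).
    Ventricle volumes are analyzed on the natural-log scale; the FA model
    drops the slice-thickness dummy (FA acquisition does not vary by slice
    protocol).
    """
    data = phenotypes.merge(volumes, on="id")
    iq_groups, _ = median_split(data)
    data = data.assign(iq_group=iq_groups)
    no_outliers, _ = exclude_iq_outliers(data)
    if measures is None:
        measures = [c for c in volumes.columns if c != "id"]

    rows = []
    for measure in measures:
        transform = "log" if measure in LOG_MEASURES else "none"
        covars = ("age", "sex", "hand", "slice_dummy")
        if measure == "cerebral_fa":
            covars = ("age", "sex", "hand")
        base_terms = ("intercept", "group", *covars)
        row = {"measure": measure}
        for diagnosis in ("control", "ADHD"):
            for label, mask in (
                ("all", data["diagnosis"] == diagnosis),
                ("below", (data["diagnosis"] == diagnosis) & (data["iq_group"] == "below")),
                ("above", (data["diagnosis"] == diagnosis) & (data["iq_group"] == "above")),
            ):
                vals = data.loc[mask, measure].dropna()
                row[f"{diagnosis}_{label}_mean"] = float(vals.mean())
                row[f"{diagnosis}_{label}_sd"] = float(vals.std(ddof=1))
        base = fit_glm(data, GlmSpec(measure, base_terms, transform))
        row["p_group"] = base.p("group")
        row["adjusted_mean_control"] = base.adjusted_means["control"]
        row["adjusted_mean_adhd"] = base.adjusted_means["ADHD"]
        row["pct_reduction_adjusted"] = (
            percent_reduction(
                base.adjusted_means["control"], base.adjusted_means["ADHD"]
            )
            if base.adjusted_means["control"] > 0
            else float("nan")
        )
        for split in ("below", "above"):
            sub = data.loc[data["iq_group"] == split]
            try:
                res = fit_glm(sub, GlmSpec(measure, base_terms, transform))
                row[f"p_group_{split}"] = res.p("group")
            except (DegenerateDesignError, CollinearityError):
                row[f"p_group_{split}"] = float("nan")
        inter = fit_glm(
            data, GlmSpec(measure, (*base_terms, "group_x_age"), transform)
        )
        row["p_group_x_age"] = inter.p("group_x_age")
        dim = dimensional_iq_model(
            no_outliers, measure, transform=transform, covariates=covars
        )
        row["p_iq"] = dim.p("iq")
        row["p_iq_x_group"] = dim.p("iq_x_group")
        rows.append(row)
    return pd.DataFrame(rows)
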