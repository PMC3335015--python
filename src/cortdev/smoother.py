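"""Locally-weighted running-line smoother with effective-df control.

The smoother fits, at every evaluation age, a weighted least-squares straight
line over a neighborhood of nearby observations and reports the line's value
at that age.  Neighborhood size is controlled by ``span`` (the fraction of
observations entering each local fit); distance weights are tricube.  Because
every fitted value is a fixed linear combination of the observations, the
whole fit is a linear operator S with y_hat = S y, and its flexibility is
summarized by the effective degrees of freedom trace(S): 1 for a constant
fit, 2 for a global straight line, larger for wigglier curves.

Model selection walks an ascending df ladder (1, 2, 2.2, 2.4, ...) and keeps
the smallest df that is not significantly improved upon by the next rung,
using the approximate nested F comparison for linear smoothers.

Implementation notes
--------------------
* The local bandwidth is the (fractionally interpolated) distance to the
  ``span * n``-th nearest neighbor, which makes trace(S) vary continuously
  with span and lets a bisection hit fractional df targets such as 2.2.
* ``span`` may exceed 1: the bandwidth is then inflated beyond the data
  range, so the tricube weights flatten and trace(S) approaches 2 (the
  global-line limit).  This is how df targets just above 2 are reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InvalidArgumentError

#: convergence tolerance for span_for_df, in df units
DF_TOL = 0.01


def default_ladder(df_max: float = 5.0) -> list[float]:
    """The default candidate-df ladder: 1, 2, then 2.2, 2.4, ... up to df_max."""
    ladder = [1.0, 2.0]
    step = 22
    while step / 10.0 <= df_max + 1e-9:
        ladder.append(step / 10.0)
        step += 2
    return ladder


def _as_ages(ages) -> np.ndarray:
    a = np.asarray(ages, dtype=float)
    if a.ndim != 1:
        raise InvalidArgumentError("ages must be one-dimensional")
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError("ages must be finite")
    return a


def smoother_matrix(ages, span: float, eval_points=None) -> np.ndarray:
    """Linear operator of the running-line smoother.

    Row i holds the weights that, applied to the observation vector, give the
    local weighted-least-squares line fit around ``eval_points[i]`` evaluated
    at that point.  Rows reproduce constants exactly and, because the local
    fit is linear, reproduce any affine function of age exactly.

    Parameters
    ----------
    ages : array-like, shape (n,)
        Observation ages (ties allowed, any order).
    span : float
        Fraction of observations in each local neighborhood; ``span * n``
        must be >= 2.  Values above 1 inflate the bandwidth beyond the data
        range (global-line limit).
    eval_points : array-like, optional
        Where to evaluate the smoother; defaults to ``ages`` (giving the
        square operator whose trace is the effective df).
    """
    a = _as_ages(ages)
    n = a.size
    if n < 3:
        raise InvalidArgumentError("need at least 3 observations")
    if span <= 0:
        raise InvalidArgumentError("span must be positive")
    r = span * n
    if r < 2.0 - 1e-9:
        raise InvalidArgumentError(
            f"span*n = {r:.3g} < 2: cannot fit a local line"
        )
    x = a if eval_points is None else _as_ages(eval_points)

    # Pairwise distances from each evaluation point to every observation.
    D = np.abs(x[:, None] - a[None, :])  # (m, n)
    Ds = np.sort(D, axis=1)
    # Fractional k-th nearest-neighbor bandwidth; for r > n extrapolate
    # linearly so the bandwidth keeps growing and weights flatten.
    if r >= n:
        h = Ds[:, -1] * (r / n)
    else:
        k = int(np.floor(r))
        frac = r - k
        if k >= n:
            h = Ds[:, -1]
        else:
            h = Ds[:, k - 1] + frac * (Ds[:, k] - Ds[:, k - 1])

    Z = a[None, :] - x[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(h[:, None] > 0, D / h[:, None], np.inf)
    W = np.clip(1.0 - U**3, 0.0, None) ** 3
    # Massive ties can make the bandwidth zero: fall back to uniform weights
    # over the zero-distance points.  A bandwidth that leaves fewer than two
    # points with positive weight gets the two nearest points uniformly.
    deg = W > 0
    bad = (h <= 0) | (deg.sum(axis=1) < 2)
    if np.any(bad):
        for i in np.flatnonzero(bad):
            if h[i] <= 0:
                W[i] = (D[i] == 0).astype(float)
            if (W[i] > 0).sum() < 2:
                nearest = np.argsort(D[i], kind="stable")[:2]
                W[i] = 0.0
                W[i, nearest] = 1.0

    S0 = W.sum(axis=1)
    S1 = (W * Z).sum(axis=1)
    S2 = (W * Z * Z).sum(axis=1)
    denom = S0 * S2 - S1 * S1
    scale = np.maximum(S0 * S2, 1e-300)
    L = np.empty_like(W)
    singular = denom <= 1e-12 * scale
    ok = ~singular
    L[ok] = W[ok] * (S2[ok, None] - S1[ok, None] * Z[ok]) / denom[ok, None]
    if np.any(singular):
        L[singular] = W[singular] / S0[singular, None]
    return L


def effective_df(operator) -> float:
    """Effective degrees of freedom of a linear smoother: trace of its matrix."""
    S = np.asarray(operator, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidArgumentError("operator must be a square matrix")
    return float(np.trace(S))


def _trace_at_span(a: np.ndarray, span: float) -> float:
    """Trace of the smoother without materializing off-diagonal work.

    Kept equivalent to ``effective_df(smoother_matrix(a, span))`` — the full
    matrix route is cheap enough that we simply reuse it.
    """
    return effective_df(smoother_matrix(a, span))


@dataclass(frozen=True)
class SpanResult:
    """Outcome of inverting the span -> effective-df map."""

    span: float
    achieved_df: float
    converged: bool  #: True when |achieved_df - target| <= DF_TOL


_span_cache: dict[tuple[bytes, float], SpanResult] = {}


def span_for_df(ages, target_df: float) -> SpanResult:
    """Find the span whose smoother has the requested effective df.

    Exploits the monotone decrease of trace(S) in span and bisects until the
    achieved df is within ``DF_TOL`` of the target.  Neighbor-count
    discretization can in principle make a target unreachable; the nearest
    achievable span is then returned with ``converged=False``.

    df targets of exactly 1 (constant) and 2 (straight line) are handled
    parametrically by :func:`fit_trajectory`, not here.
    """
    a = _as_ages(ages)
    n = a.size
    if not (2.0 < target_df < n):
        raise InvalidArgumentError(
            f"target_df must lie strictly between 2 and n={n}"
        )
    key = (a.tobytes(), float(target_df))
    hit = _span_cache.get(key)
    if hit is not None:
        return hit

    lo = 2.0 / n  # wiggliest allowed fit -> largest df
    hi = 1.0
    df_hi = _trace_at_span(a, hi)
    while df_hi > target_df and hi < 4096:
        hi *= 2.0
        df_hi = _trace_at_span(a, hi)
    df_lo = _trace_at_span(a, lo)

    best = SpanResult(lo, df_lo, abs(df_lo - target_df) <= DF_TOL)
    if abs(df_hi - target_df) < abs(best.achieved_df - target_df):
        best = SpanResult(hi, df_hi, abs(df_hi - target_df) <= DF_TOL)
    for _ in range(80):
        if best.converged:
            break
        mid = 0.5 * (lo + hi)
        df_mid = _trace_at_span(a, mid)
        if abs(df_mid - target_df) < abs(best.achieved_df - target_df):
            best = SpanResult(mid, df_mid, abs(df_mid - target_df) <= DF_TOL)
        if df_mid > target_df:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    _span_cache[key] = best
    return best


@dataclass
class SmootherFit:
    """One semiparametric age fit: curve, residuals and effective df.

    ``kind`` is ``constant`` (df exactly 1), ``line`` (df exactly 2) or
    ``smooth`` (running-line smoother at the span matching the requested df).
    """

    kind: str
    df: float  #: requested ladder df
    effective_df: float  #: achieved trace of the smoother operator
    span: float | None
    fitted_values: np.ndarray
    rss: float
    n: int
    ages: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    _coef: np.ndarray | None = field(default=None, repr=False)
    tss: float = 0.0  #: total sum of squares about the mean (scale reference)

    def predict(self, new_ages) -> np.ndarray:
        """Evaluate the fitted curve at new ages."""
        x = _as_ages(new_ages)
        if self.kind == "constant":
            return np.full(x.shape, float(np.mean(self.y)))
        if self.kind == "line":
            return np.polyval(self._coef, x)
        L = smoother_matrix(self.ages, self.span, eval_points=x)
        return L @ self.y


def fit_trajectory(ages, y, df: float) -> SmootherFit:
    """Fit the age trajectory at a given ladder df.

    df = 1 is the constant (mean) fit, df = 2 the ordinary least-squares
    line, and df > 2 the running-line smoother at ``span_for_df``.
    """
    a = _as_ages(ages)
    v = np.asarray(y, dtype=float)
    if v.shape != a.shape:
        raise InvalidArgumentError("ages and y must have equal length")
    n = a.size
    if n < 3:
        raise DegenerateDesignError("need at least 3 observations")
    if df >= 2 and np.ptp(a) == 0:
        raise DegenerateDesignError("all ages identical: only df=1 is fittable")

    if df == 1:
        fitted = np.full(n, v.mean())
        fit = SmootherFit("constant", 1.0, 1.0, None, fitted, 0.0, n, a, v)
    elif df == 2:
        coef = np.polyfit(a, v, 1)
        fitted = np.polyval(coef, a)
        fit = SmootherFit("line", 2.0, 2.0, None, fitted, 0.0, n, a, v, coef)
    elif df > 2:
        sr = span_for_df(a, df)
        S = smoother_matrix(a, sr.span)
        fitted = S @ v
        fit = SmootherFit(
            "smooth", float(df), sr.achieved_df, sr.span, fitted, 0.0, n, a, v
        )
    else:
        raise InvalidArgumentError(f"df must be >= 1, got {df}")
    fit.rss = float(((v - fitted) ** 2).sum())
    fit.tss = float(((v - v.mean()) ** 2).sum())
    return fit


def nested_f_test(fit_small: SmootherFit, fit_big: SmootherFit) -> tuple[float, float]:
    """Approximate F comparison of two nested-flexibility smoother fits.

    F = [(rss_small - rss_big) / (df_big - df_small)] / [rss_big / (n - df_big)]
    with p from the F(df_big - df_small, n - df_big) law.  A negative
    numerator (possible with smoothers, which do not minimize RSS) is clamped
    to F = 0, p = 1 — the conservative, non-rejecting outcome.
    """
    if fit_small.n != fit_big.n:
        raise InvalidArgumentError("fits compare different sample sizes")
    df_s, df_b = fit_small.effective_df, fit_big.effective_df
    if df_b <= df_s:
        raise InvalidArgumentError("fit_big must have larger effective df")
    n = fit_big.n
    if n - df_b <= 0:
        raise InvalidArgumentError("no residual degrees of freedom")
    # a fit whose residual is already at machine noise cannot be improved on
    floor = 1e-12 * max(fit_small.tss, fit_big.tss)
    if fit_small.rss <= floor:
        return 0.0, 1.0
    num = (fit_small.rss - fit_big.rss) / (df_b - df_s)
    if num <= 0 or fit_big.rss <= floor:
        if num > 0 and fit_big.rss <= floor:
            return float("inf"), 0.0
        return 0.0, 1.0
    F = num / (fit_big.rss / (n - df_b))
    p = float(stats.f.sf(F, df_b - df_s, n - df_b))
    return float(F), p


@dataclass(frozen=True)
class StepTest:
    """One rung-to-rung comparison of the df ladder walk."""

    df_from: float
    df_to: float
    f_stat: float
    p_value: float
    rejected: bool


@dataclass
class DfSelection:
    """Result of the parsimony walk up the df ladder."""

    ladder: list[float]
    chosen_df: float
    step_tests: list[StepTest]
    alpha: float
    fit: SmootherFit  #: the fit at the chosen df


def select_df(ages, y, ladder=None, alpha: float = 0.05) -> DfSelection:
    """Parsimony-based df selection along an ascending ladder.

    Starting from the df=1 constant fit, each candidate is tested against the
    immediately preceding (smaller-df) candidate with :func:`nested_f_test`;
    the walk stops at the first non-rejection and the chosen df is the last
    candidate that was still a significant improvement (df=1 if the very
    first step already fails).
    """
    if ladder is None:
        ladder = default_ladder()
    ladder = [float(d) for d in ladder]
    if sorted(ladder) != ladder or len(set(ladder)) != len(ladder):
        raise InvalidArgumentError("ladder must be strictly ascending")
    if ladder[0] != 1.0:
        raise InvalidArgumentError("ladder must start at df=1")
    if not (0 < alpha < 1):
        raise InvalidArgumentError("alpha must lie in (0, 1)")

    current = fit_trajectory(ages, y, ladder[0])
    steps: list[StepTest] = []
    for df_next in ladder[1:]:
        candidate = fit_trajectory(ages, y, df_next)
        F, p = nested_f_test(current, candidate)
        rejected = p < alpha
        steps.append(StepTest(current.df, df_next, F, p, rejected))
        if not rejected:
            break
        current = candidate
    return DfSelection(ladder, current.df, steps, alpha, current)
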