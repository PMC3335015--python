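"""Running-line smoother: operator properties, df control, model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cortdev import (
    default_ladder,
    effective_df,
    fit_trajectory,
    nested_f_test,
    select_df,
    smoother_matrix,
    span_for_df,
)
from cortdev.errors import DegenerateDesignError, InvalidArgumentError


def brute_force_row(ages, span, x):
    """Independent per-row oracle: explicit weighted LS line through lstsq.

    Recomputes the tricube neighborhood weights from their definition and
    solves the local line fit as a dense least-squares problem, without any
    of the closed-form row algebra used by ``smoother_matrix``.
    """
    a = np.asarray(ages, float)
    n = a.size
    r = span * n
    d = np.abs(a - x)
    ds = np.sort(d)
    if r >= n:
        h = ds[-1] * (r / n)
    else:
        k = int(np.floor(r))
        h = ds[k - 1] + (r - k) * (ds[k] - ds[k - 1])
    w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
    X = np.column_stack([np.ones(n), a - x])
    sw = np.sqrt(w)
    # row of the evaluation functional: e1' (X'WX)^-1 X'W
    beta_op = np.linalg.pinv(sw[:, None] * X) * sw[None, :]
    return beta_op[0]


class TestSmootherMatrix:
    def test_rows_match_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for n, span in [(20, 0.5), (50, 0.3), (35, 0.8)]:
            ages = np.sort(rng.uniform(6, 14, n))
            S = smoother_matrix(ages, span)
            for i in range(n):
                row = brute_force_row(ages, span, ages[i])
                assert np.allclose(S[i], row, atol=1e-10)

    def test_reproduces_constants_and_affine(self):
        ages = np.linspace(6, 14, 20)
        for span in (0.3, 0.5, 1.0):
            S = smoother_matrix(ages, span)
            assert np.allclose(S @ np.ones(20), 1.0)
            assert np.allclose(S @ (2 * ages - 3), 2 * ages - 3)

    def test_large_span_approaches_global_line_hat(self):
        ages = np.linspace(0, 1, 25)
        xc = ages - ages.mean()
        hat = 1 / 25 + np.outer(xc, xc) / (xc**2).sum()
        S = smoother_matrix(ages, 500.0)
        assert np.allclose(S, hat, atol=1e-3)
        assert effective_df(S) == pytest.approx(2.0, abs=1e-3)

    def test_handles_ties_in_age(self):
        ages = np.array([7.0, 7.0, 7.0, 9.0, 9.0, 11.0])
        S = smoother_matrix(ages, 0.6)
        assert np.allclose(S @ np.ones(6), 1.0)

    def test_too_small_neighborhood_rejected(self):
        with pytest.raises(InvalidArgumentError):
            smoother_matrix(np.linspace(0, 1, 30), 0.01)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(6, 15), min_size=5, max_size=40),
        st.sampled_from([0.3, 0.5, 0.8, 1.0]),
    )
    def test_affine_reproduction_property(self, age_list, span):
        ages = np.asarray(age_list)
        if span * ages.size < 2:
            return
        S = smoother_matrix(ages, span)
        target = 0.7 * ages + 1.1
        assert np.allclose(S @ target, target, atol=1e-8)


class TestEffectiveDf:
    def test_constant_and_line_operators(self):
        n = 12
        assert effective_df(np.full((n, n), 1 / n)) == pytest.approx(1.0)
        ages = np.linspace(6, 14, n)
        xc = ages - ages.mean()
        hat = 1 / n + np.outer(xc, xc) / (xc**2).sum()
        assert effective_df(hat) == pytest.approx(2.0)

    def test_monotone_decreasing_in_span(self):
        ages = np.linspace(6, 14, 50)
        dfs = [effective_df(smoother_matrix(ages, s)) for s in (0.3, 0.5, 0.8)]
        assert dfs[0] > dfs[1] > dfs[2]
        assert all(2 < d < 50 for d in dfs)

    def test_non_square_rejected(self):
        with pytest.raises(InvalidArgumentError):
            effective_df(np.ones((3, 4)))


class TestSpanForDf:
    @pytest.mark.parametrize("target", [2.2, 2.6, 3.0, 4.0, 6.0])
    def test_round_trip_within_tolerance(self, target):
        ages = np.linspace(6, 14, 100)
        res = span_for_df(ages, target)
        achieved = effective_df(smoother_matrix(ages, res.span))
        assert achieved == pytest.approx(res.achieved_df)
        assert abs(achieved - target) <= 0.01

    def test_deterministic(self):
        ages = np.linspace(6, 14, 40)
        assert span_for_df(ages, 3.0) == span_for_df(ages, 3.0)

    def test_out_of_range_targets_rejected(self):
        ages = np.linspace(6, 14, 20)
        for bad in (2.0, 1.0, 20.0, 25.0):
            with pytest.raises(InvalidArgumentError):
                span_for_df(ages, bad)


class TestFitTrajectory:
    def test_constant_fit_is_mean(self):
        fit = fit_trajectory([6.0, 8.0, 10.0], [1.0, 2.0, 3.0], 1.0)
        assert np.allclose(fit.fitted_values, 2.0)
        assert fit.rss == pytest.approx(2.0)
        assert fit.effective_df == 1.0

    def test_line_fit_exact_on_noise_free_line(self):
        ages = np.linspace(6, 14, 15)
        fit = fit_trajectory(ages, 2 * ages, 2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.effective_df == 2.0

    def test_smooth_fit_beats_line_on_curved_truth(self):
        ages = np.arange(6.0, 15.0)
        y = (ages - 10) ** 2
        rss3 = fit_trajectory(ages, y, 3.0).rss
        rss2 = fit_trajectory(ages, y, 2.0).rss
        assert rss3 < rss2

    def test_rss_non_increasing_along_ladder(self):
        rng = np.random.default_rng(5)
        ages = np.sort(rng.uniform(6, 14, 60))
        y = 3.3 + 0.2 * np.exp(-((ages - 9) ** 2) / 4) + rng.normal(0, 0.05, 60)
        rss = [fit_trajectory(ages, y, d).rss for d in default_ladder()]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        ages = rng.uniform(6, 14, 30)
        y = np.sin(ages) + rng.normal(0, 0.1, 30)
        perm = rng.permutation(30)
        fit = fit_trajectory(ages, y, 3.0)
        fit_p = fit_trajectory(ages[perm], y[perm], 3.0)
        assert fit_p.rss == pytest.approx(fit.rss, rel=1e-10)
        assert np.allclose(fit_p.fitted_values, fit.fitted_values[perm])

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_trajectory([7.0, 7.0, 7.0], [1.0, 2.0, 3.0], 2.0)
        with pytest.raises(DegenerateDesignError):
            fit_trajectory([6.0, 7.0], [1.0, 2.0], 1.0)

    def test_predict_interpolates_curve(self):
        ages = np.linspace(6, 14, 40)
        y = 2 * ages + 1
        fit = fit_trajectory(ages, y, 2.0)
        assert np.allclose(fit.predict([7.3, 12.1]), [15.6, 25.2])


class TestNestedFTest:
    def test_equal_rss_gives_null_result(self):
        ages = np.linspace(6, 14, 10)
        y = np.full(10, 3.3)
        f1 = fit_trajectory(ages, y, 1.0)
        f2 = fit_trajectory(ages, y, 2.0)
        F, p = nested_f_test(f1, f2)
        assert (F, p) == (0.0, 1.0)

    def test_matches_closed_form_ols_slope_f(self):
        ages = np.arange(10, dtype=float)
        y = np.array([2.1, 1.9, 3.2, 2.8, 3.9, 4.4, 4.1, 5.2, 5.5, 6.3])
        F, p = nested_f_test(
            fit_trajectory(ages, y, 1.0), fit_trajectory(ages, y, 2.0)
        )
        # classical slope F from first principles
        b = np.cov(ages, y, ddof=1)[0, 1] / np.var(ages, ddof=1)
        a = y.mean() - b * ages.mean()
        rss = ((y - a - b * ages) ** 2).sum()
        F_ols = (b**2 * ((ages - ages.mean()) ** 2).sum()) / (rss / 8)
        assert F == pytest.approx(F_ols, abs=1e-10)
        assert p == pytest.approx(float(stats.f.sf(F_ols, 1, 8)), abs=1e-12)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        ages = np.linspace(6, 14, 25)
        for _ in range(2000):
            y = rng.normal(3.3, 0.1, 25)
            _, p = nested_f_test(
                fit_trajectory(ages, y, 1.0), fit_trajectory(ages, y, 2.0)
            )
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSelectDf:
    def test_noise_free_line_chooses_two(self):
        ages = np.linspace(6, 14, 30)
        sel = select_df(ages, 2 * ages + 1)
        assert sel.chosen_df == 2.0
        assert sel.step_tests[0].rejected and not sel.step_tests[1].rejected

    def test_constant_null_chooses_one_at_nominal_rate(self):
        rng = np.random.default_rng(21)
        ages = np.linspace(6, 14, 40)
        chose_one = sum(
            select_df(ages, rng.normal(3.3, 0.1, 40)).chosen_df == 1.0
            for _ in range(400)
        )
        # first-step rejection rate is alpha = .05, so ~95% stay at df=1
        assert 0.90 <= chose_one / 400 <= 0.99

    def test_strong_peak_drives_selection_past_line(self):
        rng = np.random.default_rng(22)
        ages = np.linspace(6, 14, 45)
        peaked = 3.3 + 0.25 * np.exp(-((ages - 10.5) ** 2) / 8.0)
        curved = sum(
            select_df(ages, peaked + rng.normal(0, 0.01, 45)).chosen_df >= 2.2
            for _ in range(50)
        )
        assert curved > 45

    def test_ladder_validation(self):
        ages = np.linspace(6, 14, 10)
        with pytest.raises(InvalidArgumentError):
            select_df(ages, ages, ladder=[2.0, 2.2])
        with pytest.raises(InvalidArgumentError):
            select_df(ages, ages, ladder=[1.0, 2.2, 2.0])

    def test_default_ladder_shape(self):
        lad = default_ladder(3.0)
        assert lad == [1.0, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0]
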