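"""Volumetric GLMs, IQ moderation, and the small derived quantities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortdev import (
    GlmSpec,
    SimConfig,
    corrected_medication_duration,
    cortical_gm_proxy,
    dimensional_iq_model,
    exclude_iq_outliers,
    fit_glm,
    generate_cohort,
    generate_volumetrics,
    group_correlation,
    median_split,
    percent_reduction,
    summarize_volumetrics,
)
from cortdev.errors import (
    CollinearityError,
    DegenerateDesignError,
    InvalidArgumentError,
)


def _table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(6, 15, n)
    diagnosis = np.array(["control", "ADHD"] * (n // 2))
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "diagnosis": diagnosis,
            "age": age,
            "sex": rng.choice(["M", "F"], n),
            "hand": rng.choice(["R", "L", "A"], n, p=[0.8, 0.15, 0.05]),
            "iq": rng.normal(103, 13, n),
            "slice_dummy": rng.integers(0, 2, n),
            "med_months": np.nan,
        }
    )


class TestFitGlm:
    def test_noise_free_coefficients_recovered_exactly(self):
        data = _table()
        data["y"] = 2.0 * data["age"] + 5.0 * (data["diagnosis"] == "ADHD") + 7.0
        res = fit_glm(data, GlmSpec("y", ("intercept", "group", "age")))
        assert res.params["age"] == pytest.approx(2.0)
        assert res.params["group"] == pytest.approx(5.0)
        assert res.params["intercept"] == pytest.approx(7.0)
        assert res.adjusted_means["ADHD"] - res.adjusted_means["control"] == (
            pytest.approx(5.0)
        )

    def test_log_transform_requires_positive_outcome(self):
        data = _table()
        data["y"] = 0.0
        with pytest.raises(InvalidArgumentError):
            fit_glm(data, GlmSpec("y", ("intercept", "group"), transform="log"))

    def test_log_pathway_recovers_lognormal_median(self):
        rng = np.random.default_rng(4)
        data = _table(2000, seed=4)
        data["y"] = rng.lognormal(np.log(9.0), 0.5, len(data))
        res = fit_glm(
            data,
            GlmSpec("y", ("intercept", "group", "age", "sex", "hand",
                          "slice_dummy"), transform="log"),
        )
        # back-transformed adjusted mean estimates the distribution median
        for value in res.adjusted_means_response.values():
            assert value == pytest.approx(9.0, rel=0.1)

    def test_collinear_design_names_aliased_terms(self):
        data = _table()
        data["y"] = 1.0
        data["iq"] = data["age"]  # perfectly aliased with age
        with pytest.raises(CollinearityError, match="iq|age"):
            fit_glm(data, GlmSpec("y", ("intercept", "age", "iq")))

    def test_listwise_deletion_counts(self):
        data = _table()
        data["y"] = data["age"] * 1.5
        data.loc[:4, "y"] = np.nan
        res = fit_glm(data, GlmSpec("y", ("intercept", "age")))
        assert res.n_used == len(data) - 5

    def test_interaction_requires_mains(self):
        with pytest.raises(InvalidArgumentError):
            GlmSpec("y", ("intercept", "group_x_age"))

    def test_group_by_age_null_calibration(self):
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(200):
            data = _table(60, seed=seed)
            data["y"] = 3.0 + 0.5 * data["age"] + rng.normal(0, 1, 60)
            res = fit_glm(
                data, GlmSpec("y", ("intercept", "group", "age", "group_x_age"))
            )
            hits += res.p("group_x_age") < 0.05
        assert 0.01 <= hits / 200 <= 0.10


class TestDimensionalIqModel:
    def test_interaction_detected_when_slopes_differ(self):
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_per_cell=200, seed=300 + seed)
            ph = generate_cohort(cfg)
            data = ph.join(generate_volumetrics(ph, cfg).drop(columns="id"))
            data, _ = exclude_iq_outliers(data)
            res = dimensional_iq_model(data, "cerebral_gray_matter")
            hits += res.p("iq_x_group") < 0.05
        assert hits >= 8

    def test_constant_iq_rejected(self):
        data = _table()
        data["y"] = data["age"]
        data["iq"] = 100.0
        with pytest.raises(DegenerateDesignError):
            dimensional_iq_model(data, "y")


class TestMedianSplit:
    def test_median_value_goes_below(self):
        ph = pd.DataFrame({"id": list("abcd"), "iq": [90, 102, 102, 110]})
        labels, median = median_split(ph)
        assert median == 102.0
        assert labels.tolist() == ["below", "below", "below", "above"]

    def test_boundary_between_102_and_103(self):
        ph = pd.DataFrame({"id": list("abcde"),
                           "iq": [80.0, 95.0, 102.0, 103.0, 130.0]})
        labels, median = median_split(ph)
        assert median == 102.0
        assert labels.tolist() == ["below", "below", "below", "above", "above"]

    def test_odd_n_distinct_iqs_split_sizes(self):
        rng = np.random.default_rng(12)
        iq = rng.permutation(np.linspace(75, 135, 31))
        ph = pd.DataFrame({"id": [f"s{i}" for i in range(31)], "iq": iq})
        labels, median = median_split(ph)
        below = (labels == "below").sum()
        above = (labels == "above").sum()
        assert below == above + 1  # the median subject joins 'below'
        assert below == int((iq <= np.median(iq)).sum())

    def test_constant_iq_degenerate(self):
        ph = pd.DataFrame({"id": list("abc"), "iq": [100.0] * 3})
        with pytest.raises(DegenerateDesignError):
            median_split(ph)


class TestExcludeIqOutliers:
    def test_extreme_upper_value_excluded(self):
        ph = pd.DataFrame({"id": [f"s{i}" for i in range(42)],
                           "iq": list(np.linspace(80, 120, 41)) + [200.0]})
        kept, excluded = exclude_iq_outliers(ph)
        assert excluded == ["s41"]
        assert len(kept) == 41

    def test_identity_without_upper_outliers(self):
        ph = pd.DataFrame({"id": list("abcd"), "iq": [90.0, 100, 105, 115]})
        kept, excluded = exclude_iq_outliers(ph)
        assert excluded == []
        pd.testing.assert_frame_equal(kept, ph)

    def test_matches_brute_force_rule(self, study_config):
        ph = generate_cohort(study_config)
        kept, excluded = exclude_iq_outliers(ph)
        q1, q3 = np.percentile(ph["iq"], [25, 75])
        expect = ph.loc[ph["iq"] > q3 + 1.5 * (q3 - q1), "id"].tolist()
        assert excluded == expect
        # lower tail never trimmed
        assert ph["iq"].min() in kept["iq"].to_numpy()


class TestGroupCorrelation:
    def test_collinear_columns_give_unit_correlation(self):
        data = _table()
        data["y"] = 2 * data["iq"] + 1
        out = group_correlation(data, "y")
        for stats_ in out.values():
            assert stats_["r"] == pytest.approx(1.0)
            assert stats_["p"] < 1e-10

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(9)
        hits = 0
        for seed in range(300):
            data = _table(60, seed=1000 + seed)
            data["y"] = rng.normal(size=60)
            out = group_correlation(data, "y")
            hits += out["control"]["p"] < 0.05
        assert 0.01 <= hits / 300 <= 0.10

    def test_constant_column_rejected(self):
        data = _table()
        data["y"] = 1.0
        with pytest.raises(DegenerateDesignError):
            group_correlation(data, "y")


class TestDerivedQuantities:
    def test_percent_reduction_cases(self):
        assert percent_reduction(100.0, 100.0) == 0.0
        assert percent_reduction(100.0, 97.0) == pytest.approx(3.0)
        # above-median raw cell means: 748.6 vs 704.3 -> 5.92%
        assert percent_reduction(748.6, 704.3) == pytest.approx(5.92, abs=0.005)
        with pytest.raises(InvalidArgumentError):
            percent_reduction(0.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1e-3, 1e3), st.floats(0, 1e3), st.floats(1e-3, 1e3))
    def test_percent_reduction_scale_invariant(self, c, a, scale):
        assert percent_reduction(c * scale, a * scale) == pytest.approx(
            percent_reduction(c, a), abs=1e-6
        )

    def test_gm_proxy_unit_bookkeeping(self):
        assert cortical_gm_proxy(1.0, 10.0) == pytest.approx(1.0)  # 1 mm * 10 cm^2 = 1 ml
        assert cortical_gm_proxy(3.344, 1906.5) == pytest.approx(637.53, abs=0.01)
        with pytest.raises(InvalidArgumentError):
            cortical_gm_proxy(-1.0, 10.0)

    def test_corrected_medication_duration(self):
        assert corrected_medication_duration(24.0, 120.0) == pytest.approx(0.40)
        assert corrected_medication_duration(0.0, 120.0) == 0.0
        assert np.isnan(corrected_medication_duration(np.nan, 120.0))
        with pytest.raises(InvalidArgumentError):
            corrected_medication_duration(1.0, 60.0)


@pytest.fixture(scope="module")
def summary():
    cfg = SimConfig(n_per_cell=200, seed=17)
    ph = generate_cohort(cfg)
    vol = generate_volumetrics(ph, cfg)
    return summarize_volumetrics(ph, vol)


class TestSummarizeVolumetrics:
    def test_one_row_per_measure(self, summary):
        assert len(summary) == 13
        assert summary["measure"].is_unique

    def test_group_deficit_detected_for_gray_matter(self, summary):
        row = summary.set_index("measure").loc["cerebral_gray_matter"]
        assert row["p_group"] < 0.05
        assert row["pct_reduction_adjusted"] > 0

    def test_above_median_gm_reduction_stronger(self, summary):
        """The IQ-moderation pattern: GM deficit concentrated above median."""
        row = summary.set_index("measure").loc["cerebral_gray_matter"]
        below = (row["control_below_mean"] - row["ADHD_below_mean"]) / row[
            "control_below_mean"]
        above = (row["control_above_mean"] - row["ADHD_above_mean"]) / row[
            "control_above_mean"]
        assert above > below
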