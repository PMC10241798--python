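import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petromics as pm
from petromics.cohort_stats import StatsConfig, cohort_summary
from petromics.errors import DataError, DegenerateInputError

from _oracles import spearman_rho_oracle


class TestNormality:
    def test_too_small_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            pm.normality_test([1.0, 2.0])

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pm.normality_test([3.0] * 10)

    def test_null_retention_rate(self):
        """Normal samples pass the Shapiro-Wilk screen in >= 90% of seeds."""
        keep = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(500)
            if pm.normality_test(x).p_value > 0.05:
                keep += 1
        assert keep >= 90

    def test_power_against_exponential(self):
        reject = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(size=100)
            if pm.normality_test(x).p_value < 0.05:
                reject += 1
        assert reject >= 50 * 0.99 - 1e-9


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        r = pm.wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.degenerate and r.p_value == 1.0 and r.n_effective == 0

    def test_positive_shift_gives_positive_z(self):
        rng = np.random.default_rng(0)
        post = rng.normal(10, 2, 50)
        pre = post + 1.5  # pre exceeds post everywhere
        r = pm.wilcoxon_paired(pre, post)
        assert r.statistic > 0 and r.p_value < 1e-3

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(DegenerateInputError):
            pm.wilcoxon_paired([1, 2, 3, 4.5], [1, 2, 3, 4])

    def test_matches_scipy_on_untied_data(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(1)
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.3, 1.0, 40)
        mine = pm.wilcoxon_paired(pre, post)
        ref = scipy_wilcoxon(
            pre, post, correction=False, mode="approx", zero_method="wilcox"
        )
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_type_one_error_calibrated(self):
        """Empirical size within [0.035, 0.065] at nominal 0.05 (2000 nulls)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            pre = rng.normal(size=25)
            post = rng.normal(size=25)
            if pm.wilcoxon_paired(pre, post).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_sim <= 0.065


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert pm.spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert pm.spearman(x, -x).rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 3.0, 2.0, 4.0]
        assert pm.spearman(x, y).rho == pytest.approx(
            spearman_rho_oracle(x, y), rel=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pm.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_band_attached(self):
        r = pm.spearman(np.arange(20.0), np.arange(20.0) + 0.1)
        assert r.band == "full" and r.sign == "+"


class TestStrengthBands:
    @pytest.mark.parametrize(
        "rho,band",
        [
            (0.34, "moderate"),
            (0.54, "strong"),
            (-0.27, "low"),
            (0.46, "moderate"),
            (0.3, "moderate"),
            (0.5, "strong"),
            (0.7, "very strong"),
            (0.9, "full"),
            (0.0, "none"),
            (-1.0, "full"),
        ],
    )
    def test_banding(self, rho, band):
        assert pm.classify_strength(rho) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            pm.classify_strength(1.2)

    @given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_total_and_monotone_in_magnitude(self, a, b):
        order = ["none", "low", "moderate", "strong", "very strong", "full"]
        ba, bb = pm.classify_strength(a), pm.classify_strength(b)
        assert ba in order and bb in order
        if abs(a) <= abs(b):
            assert order.index(ba) <= order.index(bb)


class TestMannWhitney:
    def test_identical_groups_high_p(self):
        x = np.arange(30.0)
        assert pm.mann_whitney(x, x).p_value > 0.9

    def test_two_sd_shift_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        assert pm.mann_whitney(a, b).p_value < 1e-3

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            pm.mann_whitney([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            if pm.mann_whitney(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_sim <= 0.065


class TestCohortSummary:
    def test_published_cohort_composition(self, table1_clinical):
        s = cohort_summary(table1_clinical).set_index(["variable", "level"])
        assert s.loc[("n", ""), "count"] == 83
        assert s.loc[("regimen", "paclitaxel+cisplatin"), "percent"] == 93
        rec = s.loc["recurrence"]
        assert int(rec["count"].sum()) == 83
        assert s.loc[("figo", "IIIC2"), "count"] == 52

    def test_single_category_is_100_percent(self):
        df = pd.DataFrame(dict(patient_id=["a", "b"], histology=["scc", "scc"]))
        s = cohort_summary(df).set_index(["variable", "level"])
        assert s.loc[("histology", "scc"), "percent"] == 100

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            cohort_summary(pd.DataFrame())


@pytest.fixture(scope="module")
def small_cohort():
    bundle = pm.generate_cohort(pm.CohortSpec(n_patients=30, seed=4))
    features = pm.extract_bundle(bundle)
    return bundle, features


class TestRunCohortAnalysis:

    def test_report_covers_every_feature_once_per_section(self, small_cohort):
        bundle, features = small_cohort
        report = pm.run_cohort_analysis(features, bundle.clinical)
        feat_cols = [
            c
            for c in features.columns
            if c not in ("patient_id", "timepoint", "glcm_levels", "glcm_mode")
        ]
        assert sorted(report.paired_change.feature) == sorted(feat_cols)
        # correlations: 2 timepoints x 4 covariates per feature
        assert len(report.correlations) == len(feat_cols) * 8
        assert len(report.group_comparison) == len(feat_cols) * 2

    def test_deterministic(self, small_cohort):
        bundle, features = small_cohort
        r1 = pm.run_cohort_analysis(features, bundle.clinical)
        r2 = pm.run_cohort_analysis(features, bundle.clinical)
        pd.testing.assert_frame_equal(r1.correlations, r2.correlations)
        pd.testing.assert_frame_equal(r1.paired_change, r2.paired_change)

    def test_missing_timepoint_patients_excluded(self, small_cohort):
        bundle, features = small_cohort
        dropped = features[
            ~((features.patient_id == "P001") & (features.timepoint == "post"))
        ]
        report = pm.run_cohort_analysis(dropped, bundle.clinical)
        assert report.meta["n_pairs"] == 29
        assert report.meta["n_excluded"] == 1

    def test_too_few_pairs_rejected(self, small_cohort):
        bundle, features = small_cohort
        few = features[features.patient_id.isin(["P001", "P002", "P003"])]
        with pytest.raises(DataError, match="fewer than 5"):
            pm.run_cohort_analysis(few, bundle.clinical)

    def test_recurrence_coding_config(self, small_cohort):
        bundle, features = small_cohort
        r_bin = pm.run_cohort_analysis(
            features, bundle.clinical, StatsConfig(recurrence_coding="binary")
        )
        r_ord = pm.run_cohort_analysis(
            features, bundle.clinical, StatsConfig(recurrence_coding="ordinal")
        )
        c_bin = r_bin.correlations.query(
            "feature == 'pre_cov' and covariate == 'recurrence'"
        ).rho.values[0]
        c_ord = r_ord.correlations.query(
            "feature == 'pre_cov' and covariate == 'recurrence'"
        ).rho.values[0]
        assert c_bin != c_ord

    def test_report_to_dir_writes_tables(self, small_cohort, tmp_path):
        bundle, features = small_cohort
        report = pm.run_cohort_analysis(features, bundle.clinical)
        report.to_dir(tmp_path)
        for name in (
            "normality.csv",
            "paired_change.csv",
            "correlations.csv",
            "group_comparison.csv",
            "report.json",
            "summary.md",
        ):
            assert (tmp_path / name).exists()
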