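"""ICC(2,1): ANOVA oracle equivalence, categories, summaries, pooling."""

import numpy as np
import pytest

import oracles
from bcseg.radiomics.manifest import ALL_FEATURE_NAMES, FAMILY_SIZES
from bcseg.repro_stats import (
    RatingsTable,
    categorize_icc,
    feature_group_summary,
    icc_2_1,
    pool_group_means,
)


class TestICC:
    def test_perfect_agreement_gives_one(self, rng):
        col = rng.normal(size=30)
        res = icc_2_1(np.column_stack([col, col]))
        assert abs(res.icc - 1.0) < 1e-12
        assert res.category == "excellent"

    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(100):
            x = rng.normal(size=(30, 2))
            assert abs(icc_2_1(x).icc - oracles.naive_icc_2_1(x)) < 1e-10

    def test_matches_pingouin(self, rng):
        """Cross-check against the independent pingouin implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        for seed in range(5):
            r = np.random.default_rng(seed)
            base = r.normal(size=25)
            x = np.column_stack([base + r.normal(0, 0.3, 25), base + r.normal(0, 0.3, 25)])
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(25), 2),
                    "raters": np.tile(["a", "b"], 25),
                    "ratings": x.ravel(),
                }
            )
            ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                           ratings="ratings")
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
            res = icc_2_1(x)
            assert abs(res.icc - row["ICC"]) < 1e-9
            assert abs(res.ci95[0] - row[ci_col][0]) < 5e-3
            assert abs(res.ci95[1] - row[ci_col][1]) < 5e-3
            assert abs(res.p_value - row["pval"]) < 1e-9

    def test_pure_noise_column_drives_icc_to_zero(self, rng):
        """Adding large independent noise destroys agreement in expectation."""
        vals = []
        for i in range(200):
            r = np.random.default_rng(10_000 + i)
            base = r.normal(size=30)
            x = np.column_stack([base, base + r.normal(0, 20.0, 30)])
            vals.append(icc_2_1(x).icc)
        assert abs(float(np.mean(vals))) < 0.05

    def test_parameter_recovery_two_way_model(self):
        """Mean estimate over replicates recovers σ²s/(σ²s+σ²r+σ²e)."""
        s2_s, s2_r, s2_e = 1.0, 0.2, 0.3
        theory = s2_s / (s2_s + s2_r + s2_e)
        rng = np.random.default_rng(77)
        n, k, reps = 30, 2, 500
        est = []
        for _ in range(reps):
            subj = rng.normal(0, np.sqrt(s2_s), (n, 1))
            rater = rng.normal(0, np.sqrt(s2_r), (1, k))
            err = rng.normal(0, np.sqrt(s2_e), (n, k))
            est.append(icc_2_1(subj + rater + err).icc)
        mc_sem = float(np.std(est) / np.sqrt(reps))
        assert abs(float(np.mean(est)) - theory) < max(4 * mc_sem, 0.02)

    def test_invariance_to_affine_rescaling(self, rng):
        x = rng.normal(10, 2, size=(20, 2))
        a = icc_2_1(x).icc
        assert abs(icc_2_1(x + 5.0).icc - a) < 1e-12
        assert abs(icc_2_1(x * 3.0).icc - a) < 1e-12

    def test_rater_swap_symmetry(self, rng):
        x = rng.normal(size=(15, 2))
        assert abs(icc_2_1(x).icc - icc_2_1(x[:, ::-1]).icc) < 1e-12

    def test_constant_table_flagged_degenerate(self):
        res = icc_2_1(np.full((10, 2), 3.0))
        assert res.degenerate
        assert np.isnan(res.icc)
        assert res.category == "undefined"

    def test_table_validation(self):
        with pytest.raises(ValueError):
            RatingsTable(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            RatingsTable(np.array([[1.0, np.nan], [2.0, 2.0]]))


class TestCategorize:
    @pytest.mark.parametrize("value,expected", [
        (0.80, "good"),
        (0.49999, "poor"),
        (0.95, "excellent"),
        (0.50, "moderate"),
        (0.75, "good"),
        (0.90, "good"),
        (0.9000001, "excellent"),
        (-0.2, "poor"),
    ])
    def test_bins(self, value, expected):
        assert categorize_icc(value) == expected

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            categorize_icc(1.5)


class TestFamilySummary:
    def test_counts_match_published_taxonomy(self, rng):
        iccs = {n: float(rng.uniform(0.5, 1.0)) for n in ALL_FEATURE_NAMES}
        fams = feature_group_summary(iccs)
        by_name = {f.family: f for f in fams}
        assert by_name["firstorder"].n_features == 18
        assert by_name["shape"].n_features == 14
        assert by_name["glcm"].n_features == 24
        assert by_name["glrlm"].n_features == 16
        assert by_name["glszm"].n_features == 16
        assert by_name["ngtdm"].n_features == 5
        assert by_name["gldm"].n_features == 14

    def test_constant_iccs_degenerate_iqr(self):
        iccs = {n: 0.8 for n in ALL_FEATURE_NAMES}
        for f in feature_group_summary(iccs):
            assert f.median_icc == 0.8
            assert f.iqr == (0.8, 0.8)

    def test_median_within_iqr(self, rng):
        iccs = {n: float(rng.uniform(0, 1)) for n in ALL_FEATURE_NAMES}
        for f in feature_group_summary(iccs):
            assert f.iqr[0] <= f.median_icc <= f.iqr[1]

    def test_missing_feature_named(self):
        iccs = {n: 0.9 for n in ALL_FEATURE_NAMES if n != "glcm_Contrast"}
        with pytest.raises(ValueError, match="glcm_Contrast"):
            feature_group_summary(iccs)


class TestPooledMeans:
    def test_cohort_age_pooling(self):
        """140 patients at 73.5 y and 30 at 73.9 y pool to 73.6 at one decimal."""
        pooled = pool_group_means([(73.5, 140), (73.9, 30)])
        assert round(pooled, 1) == 73.6

    def test_identical_groups(self):
        assert pool_group_means([(5.0, 3), (5.0, 9)]) == 5.0

    def test_simple_average(self):
        assert pool_group_means([(0.0, 10), (10.0, 10)]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_group_means([])
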