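import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromediate import calibrated, generate_cohort, inject_missingness
from neuromediate.preprocess import (
    COGNITIVE_TESTS,
    age_equivalent,
    compute_g_factor,
    dichotomize_microbleeds,
    impute_covariables,
    ln_transform_wmh,
    zscore,
)


class TestLnTransform:
    def test_unit(self):
        assert ln_transform_wmh([1.0])[0] == pytest.approx(0.0)
        assert ln_transform_wmh([math.e])[0] == pytest.approx(1.0)

    def test_table_value(self):
        # ln(3.1) for the published median WMH volume
        assert ln_transform_wmh([3.1])[0] == pytest.approx(1.1314, abs=1e-4)

    def test_nonpositive_rejected_with_subject(self):
        s = pd.Series([2.0, 0.0, 3.0], index=[10, 11, 12])
        with pytest.raises(ValueError, match="11"):
            ln_transform_wmh(s)


class TestZscore:
    def test_simple(self):
        np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_hv_like(self):
        # mean 7.8, SD (n-1) = 0.8
        np.testing.assert_allclose(zscore([7.8, 7.0, 8.6]), [0.0, -1.0, 1.0])

    def test_moments(self, rng):
        z = zscore(rng.gamma(2.0, 1.5, size=500))
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1.0) < 1e-10

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore([2.0, 2.0, 2.0])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40).filter(
        lambda xs: np.std(xs) > 1e-6))
    def test_idempotent(self, xs):
        z1 = zscore(xs)
        np.testing.assert_allclose(zscore(z1), z1, atol=1e-10)


class TestDichotomize:
    @pytest.mark.parametrize("count,expected", [(0, 0), (1, 0), (2, 1), (17, 1)])
    def test_threshold(self, count, expected):
        assert dichotomize_microbleeds([count])[0] == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            dichotomize_microbleeds([-1])


class TestGFactor:
    def test_perfectly_correlated_pair(self, rng):
        t1 = rng.normal(size=200)
        df = pd.DataFrame({"wlt15": t1, "ldst": 2.0 * t1 + 5.0})
        res = compute_g_factor(df)
        assert res.variance_explained == pytest.approx(1.0)
        assert abs(np.corrcoef(res.scores, t1)[0, 1]) == pytest.approx(1.0)

    def test_independent_tests_variance_explained(self, rng):
        n, names = 100_000, ["stroop", "wft", "ldst", "wlt15", "ppb"]
        df = pd.DataFrame(rng.normal(size=(n, 5)), columns=names)
        res = compute_g_factor(df)
        assert res.variance_explained == pytest.approx(1.0 / 5.0, abs=0.01)

    def test_sign_flip_invariance(self, rng):
        g = rng.normal(size=400)
        df = pd.DataFrame({
            "stroop": -0.6 * g + rng.normal(0, 0.5, 400),
            "wft": 0.7 * g + rng.normal(0, 0.5, 400),
            "wlt15": 0.65 * g + rng.normal(0, 0.5, 400),
        })
        flipped = df.copy()
        flipped["stroop"] = -flipped["stroop"]
        a = compute_g_factor(df, negate=("stroop",))
        b = compute_g_factor(flipped, negate=())
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        g = rng.normal(size=300)
        df = pd.DataFrame({
            "wft": 0.7 * g + rng.normal(0, 0.5, 300),
            "ldst": 0.75 * g + rng.normal(0, 0.5, 300),
            "wlt15": 0.65 * g + rng.normal(0, 0.5, 300),
        })
        scaled = df.copy()
        scaled["ldst"] = 7.0 * scaled["ldst"] + 30.0
        a, b = compute_g_factor(df), compute_g_factor(scaled)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)

    def test_exclude_ppb(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 5)), columns=list(COGNITIVE_TESTS))
        res = compute_g_factor(df, include_ppb=False)
        assert "ppb" not in res.included_tests
        assert len(res.included_tests) == 4

    def test_orientation_higher_is_better(self, rng):
        g = rng.normal(size=500)
        df = pd.DataFrame({
            "wft": 0.7 * g + rng.normal(0, 0.5, 500),
            "wlt15": 0.65 * g + rng.normal(0, 0.5, 500),
        })
        res = compute_g_factor(df)
        assert res.loadings["wlt15"] > 0
        assert np.corrcoef(res.scores, g)[0, 1] > 0.5

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"wft": [1.0, np.nan, 2.0], "wlt15": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="complete"):
            compute_g_factor(df)

    def test_scores_are_zscores(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=["wft", "ldst", "wlt15"])
        res = compute_g_factor(df)
        assert abs(res.scores.mean()) < 1e-8
        assert res.scores.std(ddof=1) == pytest.approx(1.0)


class TestImputation:
    def test_no_missing_returns_identical_copies(self, rotterdam_cohort_small):
        imps = impute_covariables(rotterdam_cohort_small, m=3, seed=0)
        assert imps.m == 3 and imps.imputed_columns == ()
        for t in imps.completed_tables:
            pd.testing.assert_frame_equal(t, rotterdam_cohort_small)

    def test_mcar_prevalence_recovered(self):
        cfg = calibrated.rotterdam_like(n=40_000, seed=13)
        cfg.missingness = {"diabetes": 0.01}
        cohort = inject_missingness(generate_cohort(cfg), cfg)
        observed_prev = cohort["diabetes"].mean()  # pandas skips NaN
        imps = impute_covariables(cohort, m=2, seed=4, n_cycles=3)
        for t in imps.completed_tables:
            assert not t["diabetes"].isna().any()
            assert abs(t["diabetes"].mean() - observed_prev) < 0.01

    def test_nonmissing_cells_untouched(self):
        cfg = calibrated.rotterdam_like(n=2000, seed=17)
        cohort = inject_missingness(generate_cohort(cfg), cfg)
        obs = cohort["diabetes"].notna()
        imps = impute_covariables(cohort, m=2, seed=1, n_cycles=2)
        for t in imps.completed_tables:
            np.testing.assert_array_equal(
                t.loc[obs, "diabetes"].to_numpy(), cohort.loc[obs, "diabetes"].to_numpy()
            )

    def test_seeded_determinism(self):
        cfg = calibrated.rotterdam_like(n=2000, seed=19)
        cohort = inject_missingness(generate_cohort(cfg), cfg)
        a = impute_covariables(cohort, m=2, seed=5, n_cycles=2)
        b = impute_covariables(cohort, m=2, seed=5, n_cycles=2)
        for ta, tb in zip(a.completed_tables, b.completed_tables):
            pd.testing.assert_frame_equal(ta, tb)

    def test_missing_in_protected_column_rejected(self, rotterdam_cohort_small):
        bad = rotterdam_cohort_small.copy()
        bad.loc[bad.index[:5], "hv"] = np.nan
        with pytest.raises(ValueError, match="hv"):
            impute_covariables(bad, m=2, seed=0)

    def test_too_few_observed_rejected(self, rotterdam_cohort_small):
        bad = rotterdam_cohort_small.copy()
        bad["diabetes"] = bad["diabetes"].astype(float)
        bad.loc[bad.index[40:], "diabetes"] = np.nan
        with pytest.raises(ValueError, match="diabetes"):
            impute_covariables(bad, m=2, seed=0)


class TestAgeEquivalent:
    def test_equal_betas(self):
        assert age_equivalent(-0.0545, -0.0545) == pytest.approx(12.0)

    def test_published_consistency(self):
        # beta_exposure=-0.02 at the age coefficient implied by ~4.4 months
        assert age_equivalent(-0.02, -0.0545) == pytest.approx(4.40, abs=0.01)

    def test_zero_exposure_effect(self):
        assert age_equivalent(0.0, -0.05) == 0.0

    def test_zero_age_coefficient_rejected(self):
        with pytest.raises(ValueError, match="beta_age"):
            age_equivalent(0.1, 0.0)
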