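import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from neuromediate import (
    EffectDecomposition,
    FitError,
    calibrated,
    counterfactual_oracle,
    fit_mediator_model,
    fit_outcome_model,
    generate_cohort,
    natural_effects,
    proportion_mediated,
    total_effect,
)
from neuromediate.mediation import MediatorModelFit, OutcomeModelFit

from _helpers import random_dgp


class TestMediatorFit:
    def test_saturated_binary_recovers_logits(self):
        # exact cell counts: P(M=1|A=0)=0.07, P(M=1|A=1)=0.10
        a = np.repeat([0, 1], [10_000, 5_000])
        m = np.concatenate([
            np.repeat([1, 0], [700, 9_300]), np.repeat([1, 0], [500, 4_500])
        ])
        fit = fit_mediator_model(pd.DataFrame({"a": a, "m": m}), "m", "a")
        assert fit.link == "logit"
        assert fit.beta0 == pytest.approx(logit(0.07), abs=1e-4)
        assert fit.beta1 == pytest.approx(logit(0.10) - logit(0.07), abs=1e-4)

    def test_ols_consistency(self, rng):
        n = 100_000
        a = rng.binomial(1, 0.3, n)
        m = 0.15 * a + rng.normal(size=n)
        fit = fit_mediator_model(pd.DataFrame({"a": a, "m": m}), "m", "a")
        assert fit.link == "identity"
        assert abs(fit.beta1 - 0.15) < 3 * fit.se[1]
        assert fit.sigma == pytest.approx(1.0, abs=0.02)

    def test_independent_mediator_beta1_zero(self, rng):
        n = 50_000
        df = pd.DataFrame({"a": rng.binomial(1, 0.3, n), "m": rng.normal(size=n)})
        fit = fit_mediator_model(df, "m", "a")
        assert abs(fit.beta1) < 4 * fit.se[1]

    def test_rank_deficiency_rejected(self, rng):
        n = 200
        df = pd.DataFrame({"a": rng.binomial(1, 0.3, n), "m": rng.normal(size=n)})
        df["c1"] = rng.normal(size=n)
        df["c2"] = df["c1"]
        with pytest.raises(FitError, match="rank"):
            fit_mediator_model(df, "m", "a", ["c1", "c2"])

    def test_missing_cells_rejected(self, rng):
        df = pd.DataFrame({"a": [0, 1, 0], "m": [1.0, np.nan, 2.0]})
        with pytest.raises(FitError, match="missing"):
            fit_mediator_model(df, "m", "a")


class TestOutcomeFit:
    def test_null_interaction_estimated_near_zero(self, cog1_cohort_small):
        fit = fit_outcome_model(cog1_cohort_small, "y", "apoe4", "m")
        assert fit.link == "identity"
        assert abs(fit.theta3) < 4 * fit.se[3]

    def test_cog1_coefficients_recovered(self, cog1_cohort_small):
        fit = fit_outcome_model(cog1_cohort_small, "y", "apoe4", "m")
        assert abs(fit.theta1 - (-0.015)) < 3 * fit.se[1]
        assert abs(fit.theta2 - (-1.0 / 6.0)) < 3 * fit.se[2]

    def test_rare_logistic_or_recovered(self):
        cohort = generate_cohort(calibrated.dgp_dem1(n=800_000, seed=31))
        fit = fit_outcome_model(cohort, "y", "apoe4", "m")
        assert fit.link == "logit"
        assert abs(fit.theta1 - np.log(2.28)) < 3 * fit.se[1]
        assert fit.mean_outcome < 0.05


def _manual_fits(mediator_link, outcome_link, theta3=0.1, sigma=0.8):
    mfit = MediatorModelFit(
        link=mediator_link, beta0=-1.2, beta1=0.4, beta2=np.array([0.3]),
        confounders=("c",), sigma=sigma if mediator_link == "identity" else None, n=100,
    )
    ofit = OutcomeModelFit(
        link=outcome_link, theta0=-3.5, theta1=0.5, theta2=0.3, theta3=theta3,
        theta4=np.array([0.1]), confounders=("c",),
        resid_sd=1.0 if outcome_link == "identity" else None, n=100,
        mean_outcome=0.04 if outcome_link == "logit" else 0.0,
    )
    return mfit, ofit


@pytest.mark.parametrize("mlink", ["identity", "logit"])
@pytest.mark.parametrize("olink", ["identity", "logit"])
class TestDecompositionIdentity:
    def test_identity_holds_exactly(self, mlink, olink, rng):
        mfit, ofit = _manual_fits(mlink, olink)
        data = pd.DataFrame({"c": rng.normal(size=500)})
        d = natural_effects(mfit, ofit, data)
        if d.scale == "difference":
            assert d.te == pytest.approx(d.nde + d.nie, abs=1e-10)
        else:
            assert d.te == pytest.approx(d.nde * d.nie, rel=1e-10)

    def test_no_mediated_path(self, mlink, olink, rng):
        mfit, ofit = _manual_fits(mlink, olink, theta3=0.0)
        ofit.theta2 = 0.0
        data = pd.DataFrame({"c": rng.normal(size=500)})
        d = natural_effects(mfit, ofit, data)
        if d.scale == "difference":
            assert d.nie == pytest.approx(0.0, abs=1e-12)
            assert d.te == pytest.approx(d.nde, abs=1e-12)
        else:
            assert d.nie == pytest.approx(1.0, abs=1e-12)
            assert d.te == pytest.approx(d.nde, rel=1e-12)

    def test_no_interaction_consistency(self, mlink, olink, rng):
        # with theta3 = 0 the general formulas must equal the reduced forms
        mfit, ofit = _manual_fits(mlink, olink, theta3=0.0)
        data = pd.DataFrame({"c": rng.normal(size=500)})
        d = natural_effects(mfit, ofit, data)
        b1, t2 = mfit.beta1, ofit.theta2
        if mlink == "identity" and olink == "identity":
            assert d.nde == pytest.approx(ofit.theta1, abs=1e-12)
            assert d.nie == pytest.approx(t2 * b1, abs=1e-12)
        elif mlink == "identity" and olink == "logit":
            assert np.log(d.nde) == pytest.approx(ofit.theta1, abs=1e-12)
            assert np.log(d.nie) == pytest.approx(t2 * b1, abs=1e-12)
        elif mlink == "logit" and olink == "identity":
            assert d.nde == pytest.approx(ofit.theta1, abs=1e-12)


class TestNaturalEffectsRecovery:
    def test_cog1_decomposition(self, cog1_cohort_small):
        mfit = fit_mediator_model(cog1_cohort_small, "m", "apoe4")
        ofit = fit_outcome_model(cog1_cohort_small, "y", "apoe4", "m")
        d = natural_effects(mfit, ofit, cog1_cohort_small)
        # n=2e5: sampling SE of TE ~ 0.005
        assert d.nde == pytest.approx(-0.015, abs=0.02)
        assert d.nie == pytest.approx(-0.005, abs=0.005)
        assert d.te == pytest.approx(-0.020, abs=0.02)

    def test_dem1_decomposition(self):
        cohort = generate_cohort(calibrated.dgp_dem1(n=800_000, seed=33))
        mfit = fit_mediator_model(cohort, "m", "apoe4")
        ofit = fit_outcome_model(cohort, "y", "apoe4", "m")
        d = natural_effects(mfit, ofit, cohort)
        assert d.scale == "odds-ratio"
        assert d.nie == pytest.approx(1.030, abs=0.01)
        assert d.nde == pytest.approx(2.28, rel=0.08)

    @pytest.mark.parametrize("mlink,olink", [
        ("identity", "identity"), ("logit", "identity"),
        ("identity", "logit"), ("logit", "logit"),
    ])
    def test_matches_oracle_on_random_dgp(self, mlink, olink):
        # fitted decomposition vs Monte-Carlo truth of the generating DGP
        rng = np.random.default_rng(hash((mlink, olink)) % 2**31)
        cfg = random_dgp(rng, mediator_link=mlink, outcome_link=olink, n=200_000)
        cohort = generate_cohort(cfg)
        mfit = fit_mediator_model(cohort, "m", "apoe4", ["c0"])
        ofit = fit_outcome_model(cohort, "y", "apoe4", "m", ["c0"])
        d = natural_effects(mfit, ofit, cohort)
        truth = counterfactual_oracle(cfg, "y", ["m"], mc_reps=400_000, seed=17)
        n_eff = len(cohort) * (truth.counterfactual_means["y_astar_mastar"]
                               if olink == "logit" else 1.0)
        sampling_se = 4.0 / np.sqrt(n_eff)
        if d.scale == "difference":
            assert d.nie == pytest.approx(truth.nie, abs=3 * truth.mc_se + 3 * sampling_se)
            assert d.te == pytest.approx(truth.te, abs=3 * truth.mc_se + 3 * sampling_se)
        else:
            assert np.log(d.nie) == pytest.approx(
                np.log(truth.nie), abs=3 * truth.mc_se + 3 * sampling_se)
            assert np.log(d.te) == pytest.approx(
                np.log(truth.te), abs=3 * truth.mc_se + 3 * sampling_se)

    def test_common_outcome_rejected_without_override(self, rng):
        n = 5_000
        a = rng.binomial(1, 0.3, n)
        m = rng.normal(size=n)
        y = rng.binomial(1, 0.4, n)  # 40% prevalence: not rare
        df = pd.DataFrame({"a": a, "m": m, "y": y})
        mfit = fit_mediator_model(df, "m", "a")
        ofit = fit_outcome_model(df, "y", "a", "m")
        with pytest.raises(ValueError, match="rare"):
            natural_effects(mfit, ofit, df)
        with pytest.warns(UserWarning, match="rare"):
            natural_effects(mfit, ofit, df, allow_common_outcome=True)

    def test_fixed_values_reference(self, rotterdam_cohort_small):
        df = rotterdam_cohort_small
        mfit = fit_mediator_model(df, "hv", "apoe4", ["age", "icv"])
        ofit = fit_outcome_model(df, "cognition", "apoe4", "hv", ["age", "icv"])
        emp = natural_effects(mfit, ofit, df, confounder_reference="empirical")
        fixed = natural_effects(mfit, ofit, df, confounder_reference="fixed-values")
        # linear case: averaging and evaluating at means coincide
        assert emp.nde == pytest.approx(fixed.nde, abs=1e-10)


class TestProportionMediated:
    def test_zero_nie(self):
        d = EffectDecomposition(scale="difference", te=-0.015, nde=-0.015, nie=0.0, pm=0.0)
        assert proportion_mediated(d) == 0.0

    def test_full_mediation(self):
        d = EffectDecomposition(scale="difference", te=-0.005, nde=0.0, nie=-0.005, pm=1.0)
        assert proportion_mediated(d) == pytest.approx(1.0)

    def test_quarter(self):
        d = EffectDecomposition(scale="difference", te=-0.020, nde=-0.015, nie=-0.005, pm=0.25)
        assert proportion_mediated(d) == pytest.approx(0.25)

    def test_or_scale_headline(self):
        # 2.28 * 0.03 / (2.28*1.03 - 1)
        d = EffectDecomposition(scale="odds-ratio", te=2.28 * 1.03, nde=2.28, nie=1.03, pm=0.0)
        assert proportion_mediated(d) == pytest.approx(0.0507, abs=0.0005)

    def test_near_null_total_effect_warns(self):
        d = EffectDecomposition(scale="difference", te=1e-12, nde=1e-12, nie=0.0, pm=0.0)
        with pytest.warns(UserWarning, match="unstable"):
            proportion_mediated(d)


class TestTotalEffect:
    def test_null_dgp(self, rng):
        n = 20_000
        df = pd.DataFrame({"a": rng.binomial(1, 0.3, n), "y": rng.normal(size=n)})
        te = total_effect(df, "y", "a")
        assert abs(te.estimate) < 4 * te.se

    def test_cog1(self, cog1_cohort_small):
        te = total_effect(cog1_cohort_small, "y", "apoe4")
        assert te.scale == "difference"
        assert te.estimate == pytest.approx(-0.020, abs=3 * te.se)

    def test_dem1_or(self):
        cohort = generate_cohort(calibrated.dgp_dem1(n=800_000, seed=37))
        te = total_effect(cohort, "y", "apoe4")
        assert te.scale == "odds-ratio"
        assert np.log(te.estimate) == pytest.approx(np.log(2.345), abs=3 * te.se)
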