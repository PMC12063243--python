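"""Ready-made data-generating configurations.

``dgp_cog1`` .. ``dgp_cog3`` are small, analytically tractable simulations
whose true mediation quantities are hand-computable; they are used for
parameter-recovery validation of the estimators.  ``rotterdam_like`` is a
full cohort configuration calibrated to published marginal characteristics
of a population-based neuroimaging study (n=5,510; 28.3% exposure
prevalence; WMH median 3.1 ml; >=2 microbleeds 7.4% vs 10.2% by exposure).
"""

from __future__ import annotations

import math

from scipy.special import logit

from .config import (
    CognitiveTestSpec,
    ConfounderSpec,
    DGPConfig,
    FollowupSpec,
    MediatorSpec,
    MicrobleedCountSpec,
    OutcomeSpec,
)

__all__ = ["dgp_cog1", "dgp_dem1", "dgp_cog2", "dgp_cog3", "rotterdam_like"]

P_EXPOSURE = 0.283

# binary mediator prevalences shared by the calibrated DGPs
_P_M_A0 = 0.07
_P_M_A1 = 0.10
_B0 = float(logit(_P_M_A0))
_B1 = float(logit(_P_M_A1) - logit(_P_M_A0))


def _binary_mediator(name: str = "m") -> dict[str, MediatorSpec]:
    return {name: MediatorSpec(link="logit", beta0=_B0, beta1=_B1)}


def dgp_cog1(n: int = 4_000_000, seed: int = 0) -> DGPConfig:
    """Continuous cognition outcome, one binary mediator.

    Truths: NDE=-0.015, NIE=-1/6*(0.10-0.07)=-0.005, TE=-0.020, PM=25%.
    """
    return DGPConfig(
        n_subjects=n,
        seed=seed,
        p_exposure=P_EXPOSURE,
        mediators=_binary_mediator(),
        outcomes={
            "y": OutcomeSpec(
                link="identity", theta1=-0.015, theta2={"m": -1.0 / 6.0}, resid_sd=1.0
            )
        },
    )


def dgp_dem1(n: int = 4_000_000, seed: int = 0) -> DGPConfig:
    """Rare binary outcome, one binary mediator.

    Conditional ORs: exp(theta1)=2.28 (direct), exp(theta2)=2.075
    (mediator).  Truths: marginal OR_TE ~= 2.345; rare-outcome
    OR_NIE = (1+1.075*0.10)/(1+1.075*0.07) ~= 1.030; PM(OR) ~= 5.1%.
    """
    return DGPConfig(
        n_subjects=n,
        seed=seed,
        p_exposure=P_EXPOSURE,
        mediators=_binary_mediator(),
        outcomes={
            "y": OutcomeSpec(
                link="logit",
                theta0=float(logit(0.01)),
                theta1=math.log(2.28),
                theta2={"m": math.log(2.075)},
            )
        },
    )


def dgp_cog2(n: int = 4_000_000, seed: int = 0) -> DGPConfig:
    """Continuous outcome, binary + continuous mediator pair.

    Joint NIE = -(0.3*0.03 + 0.03*0.15) = -0.0135; TE = -0.05; PM = 27%.
    """
    return DGPConfig(
        n_subjects=n,
        seed=seed,
        p_exposure=P_EXPOSURE,
        mediators={
            "m1": MediatorSpec(link="logit", beta0=_B0, beta1=_B1),
            "m2": MediatorSpec(link="identity", beta1=0.15, sigma=1.0),
        },
        outcomes={
            "y": OutcomeSpec(
                link="identity",
                theta1=-0.0365,
                theta2={"m1": -0.3, "m2": -0.03},
                resid_sd=1.0,
            )
        },
    )


def dgp_cog3(n: int = 4_000_000, seed: int = 0) -> DGPConfig:
    """Continuous outcome, one continuous mediator.

    NIE = -0.04*0.15 = -0.006; TE = -0.05; PM = 12%.
    """
    return DGPConfig(
        n_subjects=n,
        seed=seed,
        p_exposure=P_EXPOSURE,
        mediators={"m": MediatorSpec(link="identity", beta1=0.15, sigma=1.0)},
        outcomes={
            "y": OutcomeSpec(
                link="identity", theta1=-0.044, theta2={"m": -0.04}, resid_sd=1.0
            )
        },
    )


def rotterdam_like(
    n: int = 5510,
    seed: int = 0,
    mediation_strength: float = 1.0,
    with_missingness: bool = True,
) -> DGPConfig:
    """Full cohort DGP with published-table-like marginals.

    ``mediation_strength`` scales every mediator->outcome coefficient
    (0 gives a no-mediation cohort with the same marginals).
    """
    s = mediation_strength
    confounders = {
        "age": ConfounderSpec("normal", mean=65.0, sd=10.9),
        "sex": ConfounderSpec("bernoulli", p=0.55),
        "education": ConfounderSpec("categorical", probs=(0.090, 0.383, 0.305, 0.222)),
        "smoking": ConfounderSpec("categorical", probs=(0.300, 0.497, 0.203)),
        "bmi": ConfounderSpec("normal", mean=27.5, sd=4.2),
        "sbp": ConfounderSpec("normal", mean=140.2, sd=21.6),
        "bp_med": ConfounderSpec("bernoulli", p=0.367),
        "nonhdl": ConfounderSpec("normal", mean=4.1, sd=1.0),
        "lipid_med": ConfounderSpec("bernoulli", p=0.253),
        "diabetes": ConfounderSpec("bernoulli", p=0.129),
        "af": ConfounderSpec("bernoulli", p=0.048),
        "stroke": ConfounderSpec("bernoulli", p=0.033),
        "icv": ConfounderSpec("normal", mean=1140.1, sd=116.1),
        "cortical_infarct": ConfounderSpec("bernoulli", p=0.03),
    }
    mediators = {
        # hippocampal volume (ml); icv-dependent, slight age decline
        "hv": MediatorSpec(
            link="identity",
            beta0=7.8 - 0.002 * 1140.1 + 0.01 * 65.0,
            beta1=-0.02,
            beta2={"icv": 0.002, "age": -0.01},
            sigma=0.75,
        ),
        # AD-signature cortical thickness (mm)
        "ct_ad": MediatorSpec(
            link="identity",
            beta0=2.5 + 0.002 * 65.0,
            beta1=-0.005,
            beta2={"age": -0.002},
            sigma=0.09,
        ),
        # WMH volume (ml), log-normal: latent model on the log scale
        "wmh": MediatorSpec(
            link="identity",
            beta0=math.log(3.1) - 0.04 * 65.0,
            beta1=0.05,
            beta2={"age": 0.04},
            sigma=0.6,
            transform="exp",
        ),
        # >=2 microbleeds: calibrated to 7.4% / 10.2% at mean age
        "mb2": MediatorSpec(
            link="logit",
            beta0=float(logit(0.074)) - 0.05 * 65.0,
            beta1=float(logit(0.102) - logit(0.074)),
            beta2={"age": 0.05},
        ),
    }
    outcomes = {
        # latent global cognition on the Z-score scale (age-detrended mean 0)
        "cognition": OutcomeSpec(
            link="identity",
            theta0=0.0545 * 65.0 - s * (0.06 * 7.8 + 1.2 * 2.5 - 0.05 * 1.13 - 0.17 * 0.082),
            theta1=-0.005,
            theta2={"hv": s * 0.06, "ct_ad": s * 1.2, "wmh": s * -0.05, "mb2": s * -0.17},
            theta3={"hv": 0.0, "ct_ad": 0.0, "wmh": 0.0, "mb2": 0.0},
            theta4={"age": -0.0545},
            resid_sd=0.85,
        ),
        # incident dementia over follow-up (~6% cumulative incidence)
        "dementia": OutcomeSpec(
            link="logit",
            theta0=-9.95 + s * (0.35 * 7.8 + 2.0 * 2.5 + 0.15 * 1.13 + 0.45 * 0.082),
            theta1=0.72,
            theta2={"hv": s * -0.35, "ct_ad": s * -2.0, "wmh": s * 0.15, "mb2": s * 0.45},
            theta3={"hv": 0.0, "ct_ad": 0.0, "wmh": 0.0, "mb2": 0.0},
            theta4={"age": 0.092},
        ),
    }
    tests = {
        "stroop": CognitiveTestSpec(loading=-0.60, noise_sd=0.75, mean=45.0, scale=12.0),
        "wft": CognitiveTestSpec(loading=0.70, noise_sd=0.70, mean=22.0, scale=5.0),
        "ldst": CognitiveTestSpec(loading=0.75, noise_sd=0.65, mean=30.0, scale=7.0),
        "wlt15": CognitiveTestSpec(loading=0.65, noise_sd=0.75, mean=8.0, scale=2.5),
        "ppb": CognitiveTestSpec(loading=0.50, noise_sd=0.85, mean=11.0, scale=1.8),
    }
    return DGPConfig(
        n_subjects=n,
        seed=seed,
        p_exposure=P_EXPOSURE,
        confounders=confounders,
        mediators=mediators,
        outcomes=outcomes,
        cognitive_tests=tests,
        cognition_outcome="cognition",
        microbleed_counts=MicrobleedCountSpec(source="mb2"),
        followup=FollowupSpec(outcome="dementia", median_years=11.0, censoring_spread=3.5,
                              max_years=15.0, p_ad=0.7),
        missingness={"diabetes": 0.010, "af": 0.010, "bp_med": 0.006} if with_missingness else {},
    )
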