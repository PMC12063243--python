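"""Shared builders for randomized property-test configurations."""

import numpy as np

from neuromediate.config import ConfounderSpec, DGPConfig, MediatorSpec, OutcomeSpec


def random_dgp(
    rng: np.random.Generator,
    mediator_link: str = "identity",
    outcome_link: str = "identity",
    n: int = 10_000,
    n_confounders: int = 1,
    with_interaction: bool = True,
) -> DGPConfig:
    """A small random DGP with moderate coefficients (rare outcome if logit)."""
    confounders = {
        f"c{i}": ConfounderSpec("normal", mean=float(rng.normal(0, 1)), sd=1.0)
        for i in range(n_confounders)
    }
    beta2 = {c: float(rng.normal(0, 0.2)) for c in confounders}
    if mediator_link == "identity":
        mspec = MediatorSpec(
            link="identity", beta0=float(rng.normal(0, 0.5)),
            beta1=float(rng.normal(0, 0.3)), beta2=beta2, sigma=float(rng.uniform(0.5, 1.5)),
        )
    else:
        mspec = MediatorSpec(
            link="logit", beta0=float(rng.normal(-1.5, 0.5)),
            beta1=float(rng.normal(0, 0.4)), beta2=beta2,
        )
    theta4 = {c: float(rng.normal(0, 0.2)) for c in confounders}
    theta3 = float(rng.normal(0, 0.1)) if with_interaction else 0.0
    if outcome_link == "identity":
        ospec = OutcomeSpec(
            link="identity", theta0=float(rng.normal(0, 0.5)),
            theta1=float(rng.normal(0, 0.3)), theta2={"m": float(rng.normal(0, 0.3))},
            theta3={"m": theta3}, theta4=theta4, resid_sd=1.0,
        )
    else:
        # intercept keeps the outcome rare so the OR approximation applies
        ospec = OutcomeSpec(
            link="logit", theta0=float(rng.normal(-4.0, 0.3)),
            theta1=float(rng.normal(0, 0.3)), theta2={"m": float(rng.normal(0, 0.3))},
            theta3={"m": theta3}, theta4=theta4,
        )
    return DGPConfig(
        n_subjects=n,
        seed=int(rng.integers(0, 2**31)),
        p_exposure=float(rng.uniform(0.2, 0.5)),
        confounders=confounders,
        mediators={"m": mspec},
        outcomes={"y": ospec},
    )
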