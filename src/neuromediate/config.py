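"""Configuration types for the synthetic-cohort data-generating process.

A :class:`DGPConfig` fully parameterizes a causal generative model

    confounders -> exposure -> mediators -> outcomes

with explicit coefficient blocks per mediator / outcome model, so that the
same object can drive both cohort generation and exact counterfactual
computation (see :mod:`neuromediate.synthetic`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ConfounderSpec",
    "MediatorSpec",
    "OutcomeSpec",
    "CognitiveTestSpec",
    "MicrobleedCountSpec",
    "FollowupSpec",
    "DGPConfig",
]


@dataclass
class ConfounderSpec:
    """Marginal distribution of one baseline covariable.

    ``dist`` is one of ``"normal"`` (uses ``mean``/``sd``), ``"bernoulli"``
    (uses ``p``) or ``"categorical"`` (uses ``probs``; levels are coded
    0..K-1 and enter linear predictors as the integer code).
    """

    dist: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5
    probs: tuple[float, ...] = ()

    def validate(self, name: str) -> None:
        if self.dist not in ("normal", "bernoulli", "categorical"):
            raise ValueError(f"confounder {name!r}: unknown dist {self.dist!r}")
        if self.dist == "normal" and not self.sd > 0:
            raise ValueError(f"confounder {name!r}: sd must be > 0, got {self.sd}")
        if self.dist == "bernoulli" and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"confounder {name!r}: p must be in [0,1], got {self.p}")
        if self.dist == "categorical":
            probs = np.asarray(self.probs, dtype=float)
            if probs.size < 2 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                raise ValueError(
                    f"confounder {name!r}: probs must be >=2 nonnegative values summing to 1"
                )


@dataclass
class MediatorSpec:
    """One mediator model: M = beta0 + beta1*A + beta2'C (+ noise / logit link).

    ``link="identity"`` draws Gaussian residual noise with SD ``sigma``;
    ``link="logit"`` draws Bernoulli with success probability
    expit(linear predictor).  ``transform="exp"`` exponentiates the latent
    identity-link value when writing the cohort column (log-normal markers
    such as WMH volume); downstream models consume the latent (log) value.
    """

    link: str = "identity"
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: dict[str, float] = field(default_factory=dict)
    sigma: float = 1.0
    transform: str = "none"

    def validate(self, name: str, confounders: dict[str, ConfounderSpec]) -> None:
        if self.link not in ("identity", "logit"):
            raise ValueError(f"mediator {name!r}: unknown link {self.link!r}")
        if self.link == "identity" and not self.sigma > 0:
            raise ValueError(f"mediator {name!r}: sigma must be > 0, got {self.sigma}")
        if self.transform not in ("none", "exp"):
            raise ValueError(f"mediator {name!r}: unknown transform {self.transform!r}")
        if self.transform == "exp" and self.link != "identity":
            raise ValueError(f"mediator {name!r}: transform='exp' requires identity link")
        for c in self.beta2:
            if c not in confounders:
                raise ValueError(f"mediator {name!r}: beta2 references undeclared confounder {c!r}")


@dataclass
class OutcomeSpec:
    """One outcome model with exposure-mediator interactions.

    Linear predictor:
        theta0 + theta1*A + sum_m theta2[m]*M_m + sum_m theta3[m]*A*M_m
               + sum_c theta4[c]*C_c
    ``link="identity"`` adds Gaussian noise with SD ``resid_sd``;
    ``link="logit"`` draws Bernoulli(expit(lp)).
    """

    link: str = "identity"
    theta0: float = 0.0
    theta1: float = 0.0
    theta2: dict[str, float] = field(default_factory=dict)
    theta3: dict[str, float] = field(default_factory=dict)
    theta4: dict[str, float] = field(default_factory=dict)
    resid_sd: float = 1.0

    def validate(
        self,
        name: str,
        confounders: dict[str, ConfounderSpec],
        mediators: dict[str, MediatorSpec],
    ) -> None:
        if self.link not in ("identity", "logit"):
            raise ValueError(f"outcome {name!r}: unknown link {self.link!r}")
        if self.link == "identity" and not self.resid_sd > 0:
            raise ValueError(f"outcome {name!r}: resid_sd must be > 0, got {self.resid_sd}")
        for m in list(self.theta2) + list(self.theta3):
            if m not in mediators:
                raise ValueError(f"outcome {name!r}: coefficient references undeclared mediator {m!r}")
        for c in self.theta4:
            if c not in confounders:
                raise ValueError(f"outcome {name!r}: theta4 references undeclared confounder {c!r}")


@dataclass
class CognitiveTestSpec:
    """Observed test score derived from the latent cognition outcome.

    score = mean + scale * (loading * g + N(0, noise_sd)).  A negative
    loading encodes a higher-is-worse test (e.g. Stroop completion time).
    """

    loading: float = 0.7
    noise_sd: float = 0.7
    mean: float = 0.0
    scale: float = 1.0

    def validate(self, name: str) -> None:
        if not self.noise_sd > 0:
            raise ValueError(f"cognitive test {name!r}: noise_sd must be > 0")
        if self.scale == 0:
            raise ValueError(f"cognitive test {name!r}: scale must be nonzero")


@dataclass
class MicrobleedCountSpec:
    """Microbleed count generation consistent with a binary >=2 mediator.

    The binary mediator named ``source`` decides whether the subject has
    >=2 bleeds; given that, count = 2 + Poisson(lam).  Subjects below the
    threshold have a single bleed with probability ``p_single``.  Lobar
    bleeds are a per-bleed binomial thinning with probability ``p_lobar``.
    """

    source: str = "mb2"
    lam: float = 1.0
    p_single: float = 0.10
    p_lobar: float = 0.75

    def validate(self, mediators: dict[str, MediatorSpec]) -> None:
        if self.source not in mediators:
            raise ValueError(f"microbleed_counts: source {self.source!r} is not a declared mediator")
        if mediators[self.source].link != "logit":
            raise ValueError(f"microbleed_counts: source {self.source!r} must be a binary (logit) mediator")
        if not self.lam > 0:
            raise ValueError("microbleed_counts: lam must be > 0")
        for fld in ("p_single", "p_lobar"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"microbleed_counts: {fld} must be in [0,1], got {v}")


@dataclass
class FollowupSpec:
    """Event/censoring times attached to the binary dementia outcome.

    Event times are uniform on (0, max_years]; censoring times are uniform
    on [median_years - censoring_spread, median_years + censoring_spread]
    clipped to (0, max_years].
    """

    outcome: str = "dementia"
    median_years: float = 11.0
    censoring_spread: float = 4.0
    max_years: float = 15.0
    p_ad: float = 0.7

    def validate(self, outcomes: dict[str, OutcomeSpec]) -> None:
        if self.outcome not in outcomes:
            raise ValueError(f"followup: outcome {self.outcome!r} is not declared")
        if outcomes[self.outcome].link != "logit":
            raise ValueError(f"followup: outcome {self.outcome!r} must be binary (logit)")
        if not self.max_years > 0:
            raise ValueError("followup: max_years must be > 0")
        if not 0 < self.median_years <= self.max_years:
            raise ValueError("followup: median_years must be in (0, max_years]")
        if self.censoring_spread < 0:
            raise ValueError("followup: censoring_spread must be >= 0")
        if not 0.0 <= self.p_ad <= 1.0:
            raise ValueError(f"followup: p_ad must be in [0,1], got {self.p_ad}")


@dataclass
class DGPConfig:
    n_subjects: int = 1000
    seed: int = 0
    p_exposure: float = 0.283
    exposure_name: str = "apoe4"
    confounders: dict[str, ConfounderSpec] = field(default_factory=dict)
    mediators: dict[str, MediatorSpec] = field(default_factory=dict)
    outcomes: dict[str, OutcomeSpec] = field(default_factory=dict)
    cognitive_tests: dict[str, CognitiveTestSpec] = field(default_factory=dict)
    cognition_outcome: str = "cognition"
    microbleed_counts: MicrobleedCountSpec | None = None
    followup: FollowupSpec | None = None
    missingness: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        """Check all invariants; raise ValueError naming the offending field."""
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0.0 <= self.p_exposure <= 1.0:
            raise ValueError(f"p_exposure must be in [0,1], got {self.p_exposure}")
        for name, spec in self.confounders.items():
            spec.validate(name)
        for name, spec in self.mediators.items():
            spec.validate(name, self.confounders)
        for name, spec in self.outcomes.items():
            spec.validate(name, self.confounders, self.mediators)
        if self.cognitive_tests:
            if self.cognition_outcome not in self.outcomes:
                raise ValueError(
                    f"cognitive_tests declared but cognition_outcome {self.cognition_outcome!r} is not an outcome"
                )
            for name, spec in self.cognitive_tests.items():
                spec.validate(name)
        if self.microbleed_counts is not None:
            self.microbleed_counts.validate(self.mediators)
        if self.followup is not None:
            self.followup.validate(self.outcomes)
        for col, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness[{col!r}] must be in [0,1], got {rate}")

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DGPConfig":
        d = dict(d)
        d["confounders"] = {k: ConfounderSpec(**_tup(v)) for k, v in d.get("confounders", {}).items()}
        d["mediators"] = {k: MediatorSpec(**v) for k, v in d.get("mediators", {}).items()}
        d["outcomes"] = {k: OutcomeSpec(**v) for k, v in d.get("outcomes", {}).items()}
        d["cognitive_tests"] = {
            k: CognitiveTestSpec(**v) for k, v in d.get("cognitive_tests", {}).items()
        }
        if d.get("microbleed_counts") is not None:
            d["microbleed_counts"] = MicrobleedCountSpec(**d["microbleed_counts"])
        if d.get("followup") is not None:
            d["followup"] = FollowupSpec(**d["followup"])
        return cls(**d)


def _tup(v: dict[str, Any]) -> dict[str, Any]:
    v = dict(v)
    if "probs" in v:
        v["probs"] = tuple(v["probs"])
    return v
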