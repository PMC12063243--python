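"""Synthetic cohort generation and exact counterfactual truths.

The generator draws a cohort from an explicit :class:`~neuromediate.config.DGPConfig`
in causal order (confounders, exposure, mediators, outcomes, derived columns),
with one independent random substream per column so that adding a column never
perturbs the draws of earlier columns.

:func:`counterfactual_oracle` computes ground-truth natural direct / indirect
effects for the same configuration by Monte-Carlo simulation of potential
outcomes Y(a, M(a*)), giving every downstream estimator an independent truth
to be checked against.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DGPConfig, MediatorSpec, OutcomeSpec

__all__ = ["MediationTruth", "generate_cohort", "counterfactual_oracle", "inject_missingness"]


def _substream(seed: int, *labels: str) -> np.random.Generator:
    """Independent RNG derived from the global seed and a column label."""
    key = tuple(
        int.from_bytes(hashlib.sha256(lbl.encode("utf-8")).digest()[:8], "big")
        for lbl in labels
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class MediationTruth:
    """Monte-Carlo ground truth for one (outcome, mediator-set) pair."""

    scale: str  # "difference" | "odds-ratio"
    te: float
    nde: float
    nie: float
    pm: float
    mc_reps: int
    mc_se: float
    counterfactual_means: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# cohort generation


def _draw_confounders(config: DGPConfig, n: int) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for name, spec in config.confounders.items():
        rng = _substream(config.seed, "confounder", name)
        if spec.dist == "normal":
            cols[name] = rng.normal(spec.mean, spec.sd, size=n)
        elif spec.dist == "bernoulli":
            cols[name] = rng.binomial(1, spec.p, size=n).astype(np.int64)
        else:  # categorical
            probs = np.asarray(spec.probs, dtype=float)
            cols[name] = rng.choice(len(probs), size=n, p=probs).astype(np.int64)
    return cols


def _mediator_lp(spec: MediatorSpec, a: np.ndarray, conf: dict[str, np.ndarray]) -> np.ndarray:
    lp = spec.beta0 + spec.beta1 * np.asarray(a, dtype=float)
    for c, coef in spec.beta2.items():
        lp = lp + coef * np.asarray(conf[c], dtype=float)
    return lp


def _outcome_lp(
    spec: OutcomeSpec,
    a: np.ndarray,
    mediators: dict[str, np.ndarray],
    conf: dict[str, np.ndarray],
) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    lp = spec.theta0 + spec.theta1 * a
    for m, coef in spec.theta2.items():
        lp = lp + coef * mediators[m]
    for m, coef in spec.theta3.items():
        lp = lp + coef * a * mediators[m]
    for c, coef in spec.theta4.items():
        lp = lp + coef * np.asarray(conf[c], dtype=float)
    return lp


def generate_cohort(config: DGPConfig) -> pd.DataFrame:
    """Draw a cohort table from ``config`` in causal order.

    Returns a DataFrame with one row per subject.  Mediators declared with
    ``transform="exp"`` are written on the exponentiated (always-positive)
    scale; their latent (log) values feed the outcome models.
    """
    config.validate()
    n = config.n_subjects

    conf = _draw_confounders(config, n)
    a = _substream(config.seed, "exposure").binomial(1, config.p_exposure, size=n).astype(np.int64)

    latent: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    for name, spec in config.mediators.items():
        rng = _substream(config.seed, "mediator", name)
        lp = _mediator_lp(spec, a, conf)
        if spec.link == "identity":
            val = lp + rng.normal(0.0, spec.sigma, size=n)
            latent[name] = val
            observed[name] = np.exp(val) if spec.transform == "exp" else val
        else:
            val = rng.binomial(1, expit(lp)).astype(np.int64)
            latent[name] = val.astype(float)
            observed[name] = val

    outcomes: dict[str, np.ndarray] = {}
    for name, spec in config.outcomes.items():
        rng = _substream(config.seed, "outcome", name)
        lp = _outcome_lp(spec, a, latent, conf)
        if spec.link == "identity":
            outcomes[name] = lp + rng.normal(0.0, spec.resid_sd, size=n)
        else:
            outcomes[name] = rng.binomial(1, expit(lp)).astype(np.int64)

    data: dict[str, np.ndarray] = {"subject_id": np.arange(n, dtype=np.int64)}
    data[config.exposure_name] = a
    data.update(conf)
    data.update(observed)
    data.update(outcomes)

    if config.cognitive_tests:
        g = outcomes[config.cognition_outcome]
        for name, tspec in config.cognitive_tests.items():
            rng = _substream(config.seed, "cognitive_test", name)
            noise = rng.normal(0.0, tspec.noise_sd, size=n)
            data[name] = tspec.mean + tspec.scale * (tspec.loading * g + noise)

    if config.microbleed_counts is not None:
        mbspec = config.microbleed_counts
        rng = _substream(config.seed, "mb_count")
        ge2 = np.asarray(observed[mbspec.source], dtype=np.int64)
        extra = rng.poisson(mbspec.lam, size=n)
        single = rng.binomial(1, mbspec.p_single, size=n)
        count = np.where(ge2 == 1, 2 + extra, single).astype(np.int64)
        data["mb_count"] = count
        lobar_rng = _substream(config.seed, "mb_lobar_count")
        data["mb_lobar_count"] = lobar_rng.binomial(count, mbspec.p_lobar).astype(np.int64)

    if config.followup is not None:
        fspec = config.followup
        rng = _substream(config.seed, "followup")
        event = np.asarray(outcomes[fspec.outcome], dtype=np.int64)
        t_event = rng.uniform(0.0, fspec.max_years, size=n)
        t_event = np.nextafter(t_event, fspec.max_years)  # open at 0
        lo = fspec.median_years - fspec.censoring_spread
        hi = fspec.median_years + fspec.censoring_spread
        t_cens = np.clip(rng.uniform(lo, hi, size=n), 1e-6, fspec.max_years)
        data["dementia_time"] = np.where(event == 1, t_event, t_cens)
        subtype_rng = _substream(config.seed, "dementia_subtype")
        is_ad = subtype_rng.binomial(1, fspec.p_ad, size=n)
        data["dementia_subtype"] = np.where(
            event == 1, np.where(is_ad == 1, "AD", "other"), "none"
        )

    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# counterfactual oracle


def _potential_mediators(
    config: DGPConfig,
    mediator_set: list[str],
    a_level: int,
    conf: dict[str, np.ndarray],
    noise: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Potential mediator values M(a_level) using common random numbers."""
    out: dict[str, np.ndarray] = {}
    for name in mediator_set:
        spec = config.mediators[name]
        lp = _mediator_lp(spec, np.full(len(noise[name]), a_level, dtype=float), conf)
        if spec.link == "identity":
            out[name] = lp + noise[name]
        else:
            out[name] = (noise[name] < expit(lp)).astype(float)
    return out


def counterfactual_oracle(
    config: DGPConfig,
    outcome: str,
    mediator_set: list[str] | tuple[str, ...] | str,
    a: int = 1,
    a_star: int = 0,
    mc_reps: int = 100_000,
    seed: int = 0,
    scale: str | None = None,
) -> MediationTruth:
    """True TE / NDE / NIE / PM for ``config`` by potential-outcome simulation.

    For each of ``mc_reps`` simulated subjects the three potential outcomes
    E[Y(a, M(a))], E[Y(a, M(a*))] and E[Y(a*, M(a*))] are computed with common
    random numbers, where M is the named mediator set; mediators outside the
    set follow the exposure level of Y (they sit on the direct path).  For a
    binary outcome the expectation is taken analytically over the Bernoulli
    outcome draw; effects are reported on the risk-difference or, by default
    for logit outcomes, the odds-ratio scale built from counterfactual risks.
    """
    config.validate()
    if outcome not in config.outcomes:
        raise ValueError(f"outcome {outcome!r} not declared in config")
    if isinstance(mediator_set, str):
        mediator_set = [mediator_set]
    mediator_set = list(mediator_set)
    for m in mediator_set:
        if m not in config.mediators:
            raise ValueError(f"mediator {m!r} not declared in config")

    ospec = config.outcomes[outcome]
    if scale is None:
        scale = "odds-ratio" if ospec.link == "logit" else "difference"
    if scale not in ("difference", "odds-ratio"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "odds-ratio" and ospec.link != "logit":
        raise ValueError("odds-ratio scale requires a binary (logit) outcome")

    warnings_: list[str] = []
    if mc_reps < 1000:
        warnings_.append(f"mc_reps={mc_reps} < 1000; Monte Carlo error may be large")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC0FFEE,)))
    n = mc_reps

    # confounders drawn fresh (population distribution, not a finite cohort)
    conf = {}
    for name, spec in config.confounders.items():
        if spec.dist == "normal":
            conf[name] = rng.normal(spec.mean, spec.sd, size=n)
        elif spec.dist == "bernoulli":
            conf[name] = rng.binomial(1, spec.p, size=n).astype(float)
        else:
            conf[name] = rng.choice(len(spec.probs), size=n, p=np.asarray(spec.probs)).astype(float)

    # common random numbers per mediator (Gaussian noise or uniform threshold)
    all_meds = list(config.mediators)
    noise = {}
    for name in all_meds:
        spec = config.mediators[name]
        noise[name] = (
            rng.normal(0.0, spec.sigma, size=n) if spec.link == "identity" else rng.uniform(size=n)
        )

    others = [m for m in all_meds if m not in mediator_set]

    def mean_outcome(a_y: int, a_m: int) -> np.ndarray:
        """Per-subject E[Y(a_y, M_set(a_m))] over the outcome noise."""
        med = _potential_mediators(config, mediator_set, a_m, conf, noise)
        med.update(_potential_mediators(config, others, a_y, conf, noise))
        lp = _outcome_lp(ospec, np.full(n, a_y, dtype=float), med, conf)
        return expit(lp) if ospec.link == "logit" else lp

    y_aa = mean_outcome(a, a)          # Y(a, M(a))
    y_aastar = mean_outcome(a, a_star)  # Y(a, M(a*))
    y_ss = mean_outcome(a_star, a_star)  # Y(a*, M(a*))

    m11, m10, m00 = float(y_aa.mean()), float(y_aastar.mean()), float(y_ss.mean())
    cfm = {"y_a_ma": m11, "y_a_mastar": m10, "y_astar_mastar": m00}

    if scale == "difference":
        nde = m10 - m00
        nie = m11 - m10
        te = nde + nie
        pm = nie / te if te != 0 else float("nan")
        se_nde = float(np.std(y_aastar - y_ss, ddof=1) / np.sqrt(n))
        se_nie = float(np.std(y_aa - y_aastar, ddof=1) / np.sqrt(n))
        se_te = float(np.std(y_aa - y_ss, ddof=1) / np.sqrt(n))
        mc_se = max(se_nde, se_nie, se_te)
    else:
        def odds(p: float) -> float:
            return p / (1.0 - p)

        nde = odds(m10) / odds(m00)
        nie = odds(m11) / odds(m10)
        te = nde * nie
        pm = nde * (nie - 1.0) / (nde * nie - 1.0) if te != 1.0 else float("nan")
        # delta-method SE of each log-odds, combined in quadrature
        ses = {}
        for key, (arr, p) in {
            "11": (y_aa, m11), "10": (y_aastar, m10), "00": (y_ss, m00)
        }.items():
            ses[key] = float(np.std(arr, ddof=1) / np.sqrt(n) / (p * (1.0 - p)))
        mc_se = max(
            np.hypot(ses["10"], ses["00"]),
            np.hypot(ses["11"], ses["10"]),
            np.hypot(ses["11"], ses["00"]),
        )

    return MediationTruth(
        scale=scale, te=te, nde=nde, nie=nie, pm=pm,
        mc_reps=mc_reps, mc_se=mc_se, counterfactual_means=cfm, warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(cohort: pd.DataFrame, config: DGPConfig) -> pd.DataFrame:
    """Apply MCAR masks to the covariables named in ``config.missingness``.

    Only declared confounders may be masked; the exposure, mediators and
    outcome columns are protected and a request to mask one is rejected.
    """
    protected = (
        {config.exposure_name}
        | set(config.mediators)
        | set(config.outcomes)
        | set(config.cognitive_tests)
        | {"mb_count", "mb_lobar_count", "dementia_time", "dementia_subtype"}
    )
    out = cohort.copy()
    for col, rate in config.missingness.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness[{col!r}] must be in [0,1], got {rate}")
        if col in protected or col not in config.confounders:
            raise ValueError(f"cannot mask non-covariable column {col!r}")
        if col not in out.columns:
            raise ValueError(f"missingness column {col!r} not present in cohort")
        rng = _substream(config.seed, "missingness", col)
        mask = rng.random(len(out)) < rate
        if mask.any():
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out
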