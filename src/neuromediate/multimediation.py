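"""Joint natural-effect decomposition for sets of mediators.

One model per mediator (given exposure and confounders) plus one outcome
model carrying every mediator and its exposure interaction.  The joint
counterfactual means are obtained by Monte-Carlo g-computation: mediator
vectors are drawn from their fitted conditional laws under each exposure
level (conditionally independent given exposure and confounders, with
common random numbers across levels) and pushed through the outcome model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .mediation import (
    EffectDecomposition,
    FitError,
    MediatorModelFit,
    _check_rank,
    _infer_link,
    _logit_fit,
    _ols,
    _pm,
    fit_mediator_model,
)

__all__ = ["JointOutcomeFit", "JointMediatorFit", "JointEffectDecomposition",
           "fit_joint", "joint_natural_effects"]

CONDITION_NUMBER_LIMIT = 1e8


@dataclass
class JointOutcomeFit:
    link: str
    theta0: float
    theta1: float
    theta2: np.ndarray  # per mediator, in mediator_names order
    theta3: np.ndarray  # exposure x mediator interactions, same order
    theta4: np.ndarray
    confounders: tuple[str, ...]
    resid_sd: float | None
    n: int
    mean_outcome: float | None = None


@dataclass
class JointMediatorFit:
    mediator_fits: list[MediatorModelFit]
    outcome_fit: JointOutcomeFit
    mediator_names: tuple[str, ...]
    exposure: str


def fit_joint(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediators: Sequence[str],
    confounders: Sequence[str] = (),
    outcome_link: str | None = None,
    mediator_links: dict[str, str] | None = None,
) -> JointMediatorFit:
    """Fit all mediator models and the joint outcome model.

    Rejects near-collinear mediator blocks via a condition-number guard on
    the standardized design matrix.
    """
    mediators = list(mediators)
    mediator_links = mediator_links or {}
    cols = [outcome, exposure, *mediators, *confounders]
    if data[cols].isna().any().any():
        raise FitError("fit_joint: data contains missing cells")

    mfits = [
        fit_mediator_model(data, m, exposure, confounders, link=mediator_links.get(m))
        for m in mediators
    ]

    y = data[outcome].to_numpy(dtype=float)
    a = data[exposure].to_numpy(dtype=float)
    M = np.column_stack([data[m].to_numpy(dtype=float) for m in mediators])
    X = np.column_stack(
        [np.ones(len(y)), a, M, a[:, None] * M]
        + [data[c].to_numpy(dtype=float) for c in confounders]
    )
    _check_rank(X, "joint outcome model")
    Xs = X[:, 1:] - X[:, 1:].mean(axis=0)
    norms = np.linalg.norm(Xs, axis=0)
    if np.any(norms == 0) or np.linalg.cond(Xs / norms) > CONDITION_NUMBER_LIMIT:
        raise FitError("fit_joint: mediator block is (near-)collinear")

    k = len(mediators)
    link = outcome_link or _infer_link(y)
    if link == "identity":
        coef, sd, _ = _ols(X, y, "joint outcome model")
        ofit = JointOutcomeFit(
            link="identity", theta0=coef[0], theta1=coef[1],
            theta2=coef[2:2 + k], theta3=coef[2 + k:2 + 2 * k], theta4=coef[2 + 2 * k:],
            confounders=tuple(confounders), resid_sd=sd, n=len(y),
            mean_outcome=float(y.mean()),
        )
    else:
        coef, _ = _logit_fit(X, y, "joint outcome model")
        ofit = JointOutcomeFit(
            link="logit", theta0=coef[0], theta1=coef[1],
            theta2=coef[2:2 + k], theta3=coef[2 + k:2 + 2 * k], theta4=coef[2 + 2 * k:],
            confounders=tuple(confounders), resid_sd=None, n=len(y),
            mean_outcome=float(y.mean()),
        )
    return JointMediatorFit(
        mediator_fits=mfits, outcome_fit=ofit,
        mediator_names=tuple(mediators), exposure=exposure,
    )


@dataclass
class JointEffectDecomposition(EffectDecomposition):
    mc_se: float = 0.0
    mc_draws: int = 0
    seed: int = 0


def joint_natural_effects(
    fit: JointMediatorFit,
    data: pd.DataFrame,
    a: float = 1.0,
    a_star: float = 0.0,
    mc_draws: int = 5,
    seed: int = 0,
) -> JointEffectDecomposition:
    """Monte-Carlo g-computation of joint NDE / NIE / TE / PM.

    For every subject's confounder row, ``mc_draws`` mediator vectors are
    drawn under exposure ``a`` and ``a_star`` with common random numbers,
    pushed through the outcome model, and averaged into the counterfactual
    means E[Y(a, M(a))], E[Y(a, M(a*))], E[Y(a*, M(a*))].  Binary outcomes
    are summarized on risks and converted to odds ratios.
    """
    n = len(data)
    total_draws = n * mc_draws
    if total_draws < 10_000:
        warnings.warn(
            f"only {total_draws} mediator draws (n*mc_draws); Monte-Carlo error may be large",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ofit = fit.outcome_fit

    # confounder contributions, fixed per subject
    med_czb = []
    for mfit in fit.mediator_fits:
        if len(mfit.confounders):
            C = np.column_stack([data[c].to_numpy(dtype=float) for c in mfit.confounders])
            med_czb.append(C @ mfit.beta2)
        else:
            med_czb.append(np.zeros(n))
    if len(ofit.confounders):
        Co = np.column_stack([data[c].to_numpy(dtype=float) for c in ofit.confounders])
        out_czb = Co @ ofit.theta4
    else:
        out_czb = np.zeros(n)

    # per-subject accumulators of E[Y] over draws, one per regime
    acc = {key: np.zeros(n) for key in ("aa", "as", "ss")}

    for _ in range(mc_draws):
        m_at = {}  # (mediator index, level) -> draws
        for j, mfit in enumerate(fit.mediator_fits):
            if mfit.link == "identity":
                z = rng.normal(0.0, mfit.sigma, size=n)
                for lvl in (a, a_star):
                    m_at[(j, lvl)] = mfit.beta0 + mfit.beta1 * lvl + med_czb[j] + z
            else:
                u = rng.uniform(size=n)
                for lvl in (a, a_star):
                    p = expit(mfit.beta0 + mfit.beta1 * lvl + med_czb[j])
                    m_at[(j, lvl)] = (u < p).astype(float)

        def outcome_mean(a_y: float, a_m: float) -> np.ndarray:
            lp = ofit.theta0 + ofit.theta1 * a_y + out_czb
            for j in range(len(fit.mediator_names)):
                mj = m_at[(j, a_m)]
                lp = lp + (ofit.theta2[j] + ofit.theta3[j] * a_y) * mj
            return expit(lp) if ofit.link == "logit" else lp

        acc["aa"] += outcome_mean(a, a)
        acc["as"] += outcome_mean(a, a_star)
        acc["ss"] += outcome_mean(a_star, a_star)

    y_aa = acc["aa"] / mc_draws
    y_as = acc["as"] / mc_draws
    y_ss = acc["ss"] / mc_draws
    m11, m10, m00 = float(y_aa.mean()), float(y_as.mean()), float(y_ss.mean())

    if ofit.link == "identity":
        nde, nie = m10 - m00, m11 - m10
        te = nde + nie
        scale = "difference"
        mc_se = max(
            float(np.std(y_as - y_ss, ddof=1) / np.sqrt(n)),
            float(np.std(y_aa - y_as, ddof=1) / np.sqrt(n)),
            float(np.std(y_aa - y_ss, ddof=1) / np.sqrt(n)),
        )
    else:
        odds = lambda p: p / (1.0 - p)
        nde = odds(m10) / odds(m00)
        nie = odds(m11) / odds(m10)
        te = nde * nie
        scale = "odds-ratio"
        ses = {
            key: float(np.std(arr, ddof=1) / np.sqrt(n) / (p * (1.0 - p)))
            for key, (arr, p) in {"11": (y_aa, m11), "10": (y_as, m10), "00": (y_ss, m00)}.items()
        }
        mc_se = max(
            float(np.hypot(ses["10"], ses["00"])),
            float(np.hypot(ses["11"], ses["10"])),
            float(np.hypot(ses["11"], ses["00"])),
        )

    pm, unstable = _pm(scale, te, nde, nie)
    return JointEffectDecomposition(
        scale=scale, te=te, nde=nde, nie=nie, pm=pm, a=a, a_star=a_star,
        confounder_reference="empirical", unstable=unstable,
        mc_se=mc_se, mc_draws=mc_draws, seed=seed,
    )
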