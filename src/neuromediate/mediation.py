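"""Regression-based counterfactual mediation estimator.

Decomposes the total effect of a binary exposure into natural direct and
indirect effects, allowing exposure-mediator interaction, for the four
model combinations (continuous/binary mediator x continuous/rare-binary
outcome).  Closed-form effects are averaged over the empirical confounder
distribution; inference is by subject-level bootstrap with percentile CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

try:  # statsmodels moved/renamed this exception across versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

__all__ = [
    "FitError",
    "MediatorModelFit",
    "OutcomeModelFit",
    "EffectDecomposition",
    "BootstrapSummary",
    "TotalEffect",
    "fit_mediator_model",
    "fit_outcome_model",
    "natural_effects",
    "proportion_mediated",
    "total_effect",
    "bootstrap",
    "pool_imputations",
    "run_single_mediation",
]


class FitError(ValueError):
    """Model fit rejected (rank deficiency, separation, non-convergence)."""


# ---------------------------------------------------------------------------
# model fits


@dataclass
class MediatorModelFit:
    link: str
    beta0: float
    beta1: float
    beta2: np.ndarray
    confounders: tuple[str, ...]
    sigma: float | None
    n: int
    se: np.ndarray | None = None


@dataclass
class OutcomeModelFit:
    link: str
    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: np.ndarray
    confounders: tuple[str, ...]
    resid_sd: float | None
    n: int
    se: np.ndarray | None = None
    mean_outcome: float | None = None


def _design(data: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols]
    )
    return X


def _check_rank(X: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"{what}: design matrix is rank deficient")


def _ols(X: np.ndarray, y: np.ndarray, what: str) -> tuple[np.ndarray, float, np.ndarray]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise FitError(f"{what}: design matrix is rank deficient")
    resid = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return coef, float(np.sqrt(sigma2)), se


def _logit_fit(X: np.ndarray, y: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    _check_rank(X, what)
    model = sm.Logit(y, X)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("newton", "lbfgs"):
            try:
                cand = model.fit(disp=0, maxiter=500, method=method)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                continue
            params = np.asarray(cand.params, dtype=float)
            if np.all(np.isfinite(params)) and cand.mle_retvals.get("converged", True):
                res = cand
                break
    if res is None:
        raise FitError(f"{what}: logistic fit did not converge (possible separation)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = np.asarray(res.bse, dtype=float)
    return np.asarray(res.params, dtype=float), bse


def _infer_link(y: np.ndarray) -> str:
    return "logit" if set(np.unique(y)).issubset({0.0, 1.0}) else "identity"


def fit_mediator_model(
    data: pd.DataFrame,
    mediator: str,
    exposure: str,
    confounders: Sequence[str] = (),
    link: str | None = None,
) -> MediatorModelFit:
    """Fit M ~ exposure + confounders (OLS or logistic, by mediator type)."""
    y = data[mediator].to_numpy(dtype=float)
    X = _design(data, [exposure, *confounders])
    if np.isnan(y).any() or np.isnan(X).any():
        raise FitError("fit_mediator_model: data contains missing cells")
    link = link or _infer_link(y)
    if link == "identity":
        coef, sigma, se = _ols(X, y, "mediator model")
        return MediatorModelFit(
            link="identity", beta0=coef[0], beta1=coef[1], beta2=coef[2:],
            confounders=tuple(confounders), sigma=sigma, n=len(y), se=se,
        )
    coef, se = _logit_fit(X, y, "mediator model")
    return MediatorModelFit(
        link="logit", beta0=coef[0], beta1=coef[1], beta2=coef[2:],
        confounders=tuple(confounders), sigma=None, n=len(y), se=se,
    )


def fit_outcome_model(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    confounders: Sequence[str] = (),
    link: str | None = None,
) -> OutcomeModelFit:
    """Fit Y ~ exposure + mediator + exposure:mediator + confounders.

    The exposure-mediator interaction is always included (its estimate may
    be near zero); this is what makes the decomposition valid when the
    direct effect differs by mediator level.
    """
    y = data[outcome].to_numpy(dtype=float)
    a = data[exposure].to_numpy(dtype=float)
    m = data[mediator].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y)), a, m, a * m]
        + [data[c].to_numpy(dtype=float) for c in confounders]
    )
    if np.isnan(y).any() or np.isnan(X).any():
        raise FitError("fit_outcome_model: data contains missing cells")
    link = link or _infer_link(y)
    if link == "identity":
        coef, sd, se = _ols(X, y, "outcome model")
        return OutcomeModelFit(
            link="identity", theta0=coef[0], theta1=coef[1], theta2=coef[2],
            theta3=coef[3], theta4=coef[4:], confounders=tuple(confounders),
            resid_sd=sd, n=len(y), se=se, mean_outcome=float(y.mean()),
        )
    coef, se = _logit_fit(X, y, "outcome model")
    return OutcomeModelFit(
        link="logit", theta0=coef[0], theta1=coef[1], theta2=coef[2],
        theta3=coef[3], theta4=coef[4:], confounders=tuple(confounders),
        resid_sd=None, n=len(y), se=se, mean_outcome=float(y.mean()),
    )


# ---------------------------------------------------------------------------
# natural effects


@dataclass
class EffectDecomposition:
    scale: str  # "difference" | "odds-ratio"
    te: float
    nde: float
    nie: float
    pm: float
    a: float = 1.0
    a_star: float = 0.0
    confounder_reference: str = "empirical"
    unstable: bool = False


RARE_OUTCOME_THRESHOLD = 0.10


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def natural_effects(
    mfit: MediatorModelFit,
    ofit: OutcomeModelFit,
    data: pd.DataFrame,
    a: float = 1.0,
    a_star: float = 0.0,
    confounder_reference: str = "empirical",
    allow_common_outcome: bool = False,
) -> EffectDecomposition:
    """Closed-form natural-effect decomposition from fitted models.

    Effects are averaged over the confounder rows of ``data``
    (``confounder_reference="empirical"``) or evaluated at their means
    (``"fixed-values"``).  Binary outcomes use the rare-outcome
    odds-ratio approximation and are rejected above 10% prevalence unless
    ``allow_common_outcome`` is set.
    """
    if confounder_reference not in ("empirical", "fixed-values"):
        raise ValueError(f"unknown confounder_reference {confounder_reference!r}")
    if ofit.link == "logit":
        prev = ofit.mean_outcome
        if prev is not None and prev > RARE_OUTCOME_THRESHOLD:
            if not allow_common_outcome:
                raise ValueError(
                    f"binary outcome prevalence {prev:.3f} exceeds the rare-outcome "
                    f"threshold {RARE_OUTCOME_THRESHOLD}; pass allow_common_outcome=True to override"
                )
            warnings.warn(
                f"binary outcome prevalence {prev:.3f} > {RARE_OUTCOME_THRESHOLD}; "
                "rare-outcome odds-ratio approximation may be poor",
                stacklevel=2,
            )

    if len(mfit.confounders) == 0:
        czb = np.zeros(1)
    else:
        C = np.column_stack([data[c].to_numpy(dtype=float) for c in mfit.confounders])
        if confounder_reference == "fixed-values":
            C = C.mean(axis=0, keepdims=True)
        czb = C @ mfit.beta2

    t1, t2, t3 = ofit.theta1, ofit.theta2, ofit.theta3
    b0, b1 = mfit.beta0, mfit.beta1
    lp_star = b0 + b1 * a_star + czb
    lp_a = b0 + b1 * a + czb
    da = a - a_star

    if ofit.link == "identity" and mfit.link == "identity":
        nde = float(np.mean((t1 + t3 * lp_star) * da))
        nie = float((t2 * b1 + t3 * b1 * a) * da)
        scale = "difference"
    elif ofit.link == "identity" and mfit.link == "logit":
        nde = float(np.mean((t1 + t3 * expit(lp_star)) * da))
        nie = float(np.mean((t2 + t3 * a) * (expit(lp_a) - expit(lp_star))))
        scale = "difference"
    elif ofit.link == "logit" and mfit.link == "logit":
        log_nde = t1 * da + np.mean(
            _log1pexp(t2 + t3 * a + lp_star) - _log1pexp(t2 + t3 * a_star + lp_star)
        )
        log_nie = np.mean(
            _log1pexp(lp_star) + _log1pexp(t2 + t3 * a + lp_a)
            - _log1pexp(lp_a) - _log1pexp(t2 + t3 * a + lp_star)
        )
        nde, nie = float(np.exp(log_nde)), float(np.exp(log_nie))
        scale = "odds-ratio"
    else:  # logit outcome, identity mediator
        s2 = mfit.sigma ** 2
        log_nde = np.mean(
            (t1 + t3 * (lp_star + t2 * s2)) * da
        ) + 0.5 * t3 ** 2 * s2 * (a ** 2 - a_star ** 2)
        log_nie = (t2 * b1 + t3 * b1 * a) * da
        nde, nie = float(np.exp(log_nde)), float(np.exp(log_nie))
        scale = "odds-ratio"

    if scale == "difference":
        te = nde + nie
    else:
        te = nde * nie
    pm, unstable = _pm(scale, te, nde, nie)
    return EffectDecomposition(
        scale=scale, te=te, nde=nde, nie=nie, pm=pm, a=a, a_star=a_star,
        confounder_reference=confounder_reference, unstable=unstable,
    )


def _pm(scale: str, te: float, nde: float, nie: float, tol: float = 1e-8) -> tuple[float, bool]:
    if scale == "difference":
        unstable = abs(te) < tol
        pm = nie / te if te != 0 else float("nan")
    else:
        unstable = abs(te - 1.0) < tol
        denom = nde * nie - 1.0
        pm = nde * (nie - 1.0) / denom if denom != 0 else float("nan")
    return pm, unstable


def proportion_mediated(d: EffectDecomposition, tol: float = 1e-8) -> float:
    """Share of the total effect carried by the mediated path.

    Difference scale: NIE/TE.  Odds-ratio scale: the excess-relative-risk
    form OR_NDE*(OR_NIE-1)/(OR_NDE*OR_NIE-1).  A total effect within
    ``tol`` of null flags the result as unstable (warning, not an error).
    """
    pm, unstable = _pm(d.scale, d.te, d.nde, d.nie, tol=tol)
    if unstable:
        warnings.warn(
            "total effect is within tolerance of the null; proportion mediated is unstable",
            stacklevel=2,
        )
    return pm


@dataclass
class TotalEffect:
    estimate: float  # beta (identity) or OR (logit)
    scale: str
    se: float  # on the coefficient / log-OR scale
    n: int


def total_effect(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    confounders: Sequence[str] = (),
    link: str | None = None,
) -> TotalEffect:
    """Confounder-adjusted exposure effect without mediator terms."""
    y = data[outcome].to_numpy(dtype=float)
    X = _design(data, [exposure, *confounders])
    if np.isnan(y).any() or np.isnan(X).any():
        raise FitError("total_effect: data contains missing cells")
    link = link or _infer_link(y)
    if link == "identity":
        coef, _, se = _ols(X, y, "total-effect model")
        return TotalEffect(estimate=float(coef[1]), scale="difference", se=float(se[1]), n=len(y))
    coef, se = _logit_fit(X, y, "total-effect model")
    return TotalEffect(estimate=float(np.exp(coef[1])), scale="odds-ratio", se=float(se[1]), n=len(y))


# ---------------------------------------------------------------------------
# bootstrap inference


@dataclass
class BootstrapSummary:
    point: float
    ci_low: float
    ci_high: float
    p_value: float
    B: int
    seed: int
    estimand: str = ""
    log_scale: bool = False
    n_failed: int = 0
    draws: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def to_dict(self) -> dict:
        return {
            "point": self.point, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p_value, "B": self.B,
        }


def _percentile_summary(
    point: float,
    draws: np.ndarray,
    B: int,
    seed: int,
    estimand: str = "",
    log_scale: bool = False,
    n_failed: int = 0,
) -> BootstrapSummary:
    good = draws[np.isfinite(draws)]
    lo, hi = np.percentile(good, [2.5, 97.5])
    null = 1.0 if log_scale else 0.0
    k = len(good)
    p = 2.0 * min(
        (np.sum(good <= null) + 1) / (k + 1),
        (np.sum(good >= null) + 1) / (k + 1),
    )
    return BootstrapSummary(
        point=point, ci_low=float(lo), ci_high=float(hi), p_value=float(min(p, 1.0)),
        B=B, seed=seed, estimand=estimand, log_scale=log_scale,
        n_failed=n_failed, draws=draws,
    )


def _bootstrap_draws(
    analysis_vec: Callable[[pd.DataFrame], np.ndarray],
    data: pd.DataFrame,
    k: int,
    B: int,
    seed: int,
    max_fail_frac: float = 0.01,
) -> tuple[np.ndarray, int]:
    """Subject-level resampling; returns (B, k) draw matrix and failure count."""
    if B < 2:
        raise ValueError(f"B must be >= 2, got {B}")
    rng = np.random.default_rng(seed)
    n = len(data)
    raw = data.reset_index(drop=True)
    draws = np.full((B, k), np.nan)
    failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            draws[b] = analysis_vec(raw.take(idx))
        except Exception:
            failed += 1
    if failed > max_fail_frac * B:
        raise RuntimeError(
            f"bootstrap: {failed}/{B} replicates failed (> {max_fail_frac:.0%} allowed)"
        )
    return draws, failed


def bootstrap(
    analysis: Callable[[pd.DataFrame], float],
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    log_scale: bool = False,
    estimand: str = "",
) -> BootstrapSummary:
    """Percentile bootstrap of a scalar statistic over subject resamples.

    The two-sided p-value counts replicates on either side of the null (0,
    or 1 when ``log_scale`` marks a ratio statistic) with a +1 continuity
    correction.  Replicates where ``analysis`` raises are dropped; more
    than 1% failures rejects the run.
    """
    point = float(analysis(data))
    vec = lambda d: np.array([analysis(d)], dtype=float)
    draws, failed = _bootstrap_draws(vec, data, 1, B, seed)
    return _percentile_summary(
        point, draws[:, 0], B, seed, estimand=estimand, log_scale=log_scale, n_failed=failed
    )


# ---------------------------------------------------------------------------
# multiple-imputation pooling


def pool_imputations(results: Sequence) -> object:
    """Pool per-imputation results into one.

    BootstrapSummaries: the point estimate is the (log-scale-aware) mean of
    the m points and the percentile CI / p-value are recomputed from the
    pooled bootstrap draws.  EffectDecompositions: effects are averaged
    (on the log scale for odds ratios) and PM recomputed.
    """
    results = list(results)
    if len(results) < 1:
        raise ValueError("pool_imputations: need at least one result")
    first = results[0]
    if isinstance(first, BootstrapSummary):
        if any(not isinstance(r, BootstrapSummary) for r in results):
            raise ValueError("pool_imputations: mixed result types")
        if any(r.estimand != first.estimand or r.log_scale != first.log_scale for r in results):
            raise ValueError("pool_imputations: mixed estimands")
        # m identical analyses (imputation was a no-op): pooling must be exact
        if all(
            r.point == first.point and np.array_equal(r.draws, first.draws)
            for r in results[1:]
        ):
            return first
        points = np.array([r.point for r in results])
        point = (
            float(np.exp(np.mean(np.log(points)))) if first.log_scale else float(points.mean())
        )
        draws = np.concatenate([r.draws for r in results])
        return _percentile_summary(
            point, draws, B=sum(r.B for r in results), seed=first.seed,
            estimand=first.estimand, log_scale=first.log_scale,
            n_failed=sum(r.n_failed for r in results),
        )
    if isinstance(first, EffectDecomposition):
        if any(not isinstance(r, EffectDecomposition) or r.scale != first.scale for r in results):
            raise ValueError("pool_imputations: mixed estimands")
        if first.scale == "difference":
            te = float(np.mean([r.te for r in results]))
            nde = float(np.mean([r.nde for r in results]))
            nie = float(np.mean([r.nie for r in results]))
        else:
            te = float(np.exp(np.mean(np.log([r.te for r in results]))))
            nde = float(np.exp(np.mean(np.log([r.nde for r in results]))))
            nie = float(np.exp(np.mean(np.log([r.nie for r in results]))))
        pm, unstable = _pm(first.scale, te, nde, nie)
        return EffectDecomposition(
            scale=first.scale, te=te, nde=nde, nie=nie, pm=pm,
            a=first.a, a_star=first.a_star,
            confounder_reference=first.confounder_reference, unstable=unstable,
        )
    raise ValueError(f"pool_imputations: unsupported result type {type(first).__name__}")


# ---------------------------------------------------------------------------
# convenience: full single-mediator analysis with joint bootstrap


def run_single_mediation(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    confounders: Sequence[str] = (),
    outcome_link: str | None = None,
    mediator_link: str | None = None,
    a: float = 1.0,
    a_star: float = 0.0,
    B: int = 1000,
    seed: int = 0,
    allow_common_outcome: bool = False,
) -> dict:
    """Fit both models, decompose, and bootstrap TE/NDE/NIE/PM jointly.

    All four estimands share the same resamples (both models are refit in
    every replicate).  Returns ``{"decomposition": EffectDecomposition,
    "te": BootstrapSummary, "nde": ..., "nie": ..., "pm": ...}``; the PM
    p-value is inherited from the NIE (the test of the mediated path).
    """

    def decompose(d: pd.DataFrame) -> EffectDecomposition:
        mfit = fit_mediator_model(d, mediator, exposure, confounders, link=mediator_link)
        ofit = fit_outcome_model(d, outcome, exposure, mediator, confounders, link=outcome_link)
        return natural_effects(
            mfit, ofit, d, a=a, a_star=a_star, allow_common_outcome=allow_common_outcome
        )

    dec = decompose(data)
    vec = lambda d: (lambda x: np.array([x.te, x.nde, x.nie, x.pm]))(decompose(d))
    draws, failed = _bootstrap_draws(vec, data, 4, B, seed)

    log_scale = dec.scale == "odds-ratio"
    out: dict = {"decomposition": dec}
    for j, name in enumerate(("te", "nde", "nie")):
        out[name] = _percentile_summary(
            getattr(dec, name), draws[:, j], B, seed,
            estimand=f"{outcome}|{mediator}|{name}", log_scale=log_scale, n_failed=failed,
        )
    pm_summary = _percentile_summary(
        dec.pm, draws[:, 3], B, seed,
        estimand=f"{outcome}|{mediator}|pm", log_scale=False, n_failed=failed,
    )
    pm_summary.p_value = out["nie"].p_value
    out["pm"] = pm_summary
    return out
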