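"""Pre-mediation transformations.

Covers the natural-log transform of WMH volume, Z-standardization of the
volumetric markers, the >=2-microbleed dichotomy, extraction of the global
cognition factor (first unrotated principal component of the test battery),
chained-equations multiple imputation of covariables, and the conversion of
an exposure coefficient into age-equivalent months of cognitive ageing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GFactorResult",
    "ImputationSet",
    "ln_transform_wmh",
    "zscore",
    "dichotomize_microbleeds",
    "compute_g_factor",
    "impute_covariables",
    "age_equivalent",
    "COGNITIVE_TESTS",
    "PPB_TEST",
]

#: canonical column names of the cognitive test battery
COGNITIVE_TESTS = ("stroop", "wft", "ldst", "wlt15", "ppb")
PPB_TEST = "ppb"

#: tests scored so that higher = worse; negated before PCA for interpretable loadings
HIGHER_IS_WORSE = ("stroop",)


def ln_transform_wmh(wmh) -> pd.Series:
    """Natural log of WMH volumes; all inputs must be strictly positive."""
    s = pd.Series(wmh, dtype=float)
    bad = s.index[~(s > 0)]
    if len(bad):
        raise ValueError(f"WMH must be > 0 for ln transform; offending subjects: {list(bad[:10])}")
    return np.log(s)


def zscore(values) -> pd.Series:
    """Standardize to mean 0, SD 1 (n-1 denominator)."""
    s = pd.Series(values, dtype=float)
    if s.isna().any():
        raise ValueError("zscore: input contains missing values")
    sd = s.std(ddof=1)
    if s.nunique() < 2 or not sd > 0:
        raise ValueError("zscore: input is constant")
    return (s - s.mean()) / sd


def dichotomize_microbleeds(counts, threshold: int = 2) -> pd.Series:
    """1 iff microbleed count >= threshold (default 2)."""
    s = pd.Series(counts)
    if (s < 0).any():
        raise ValueError("microbleed counts must be non-negative")
    return (s >= threshold).astype(np.int64)


@dataclass
class GFactorResult:
    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    included_tests: tuple[str, ...]


def compute_g_factor(
    test_scores: pd.DataFrame,
    include_ppb: bool = True,
    negate: tuple[str, ...] = HIGHER_IS_WORSE,
    orient_on: str = "wlt15",
) -> GFactorResult:
    """First unrotated principal component of the standardized test battery.

    Rows must be complete (callers filter to the complete-assessment
    subsample first).  Tests listed in ``negate`` (higher score = worse
    performance) are sign-flipped before standardization.  The component
    sign is fixed so the loading on ``orient_on`` is positive, making a
    higher score mean better cognition.  Scores are returned as Z-scores
    (mean 0, SD 1 over the complete-case sample).
    """
    cols = [c for c in test_scores.columns if include_ppb or c != PPB_TEST]
    X = test_scores[cols]
    if X.isna().any().any():
        raise ValueError("compute_g_factor requires complete rows; filter incomplete assessments first")
    if len(X) < len(cols):
        raise ValueError(f"need at least {len(cols)} complete rows, got {len(X)}")

    Z = X.astype(float).copy()
    for c in cols:
        if c in negate:
            Z[c] = -Z[c]
        Z[c] = zscore(Z[c])

    corr = Z.to_numpy().T @ Z.to_numpy() / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    var_explained = float(eigvals[-1] / eigvals.sum())

    anchor = orient_on if orient_on in cols else cols[0]
    if v[cols.index(anchor)] < 0:
        v = -v

    raw = Z.to_numpy() @ v
    scores = pd.Series((raw - raw.mean()) / raw.std(ddof=1), index=X.index, name="g")
    loadings = pd.Series(v, index=cols, name="loading")
    return GFactorResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_explained,
        included_tests=tuple(cols),
    )


@dataclass
class ImputationSet:
    m: int
    completed_tables: list[pd.DataFrame]
    imputed_columns: tuple[str, ...]
    seed: int
    n_cycles: int = 10


#: columns that must never contain missing values when imputing
DEFAULT_PROTECTED = (
    ("apoe4", "hv", "ct_ad", "wmh", "mb_count", "mb_lobar_count", "mb2",
     "dementia", "dementia_time", "cognition", "g")
    + COGNITIVE_TESTS
)


def _is_binary(s: pd.Series) -> bool:
    vals = s.dropna().unique()
    return set(np.asarray(vals, dtype=float)).issubset({0.0, 1.0})


def impute_covariables(
    cohort: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    n_cycles: int = 10,
    protected: tuple[str, ...] = DEFAULT_PROTECTED,
    min_observed: int = 50,
) -> ImputationSet:
    """Chained-equations multiple imputation of covariable columns.

    Continuous targets are imputed by linear regression with Gaussian
    predictive draws; binary targets by logistic regression with Bernoulli
    draws.  Runs ``n_cycles`` full cycles per imputation; the ``m``
    imputations use independent substreams of ``seed``.  Missingness in a
    protected (exposure / mediator / outcome) column is rejected.
    """
    from sklearn.linear_model import LinearRegression, LogisticRegression

    numeric = cohort.select_dtypes(include=[np.number])
    na_cols = [c for c in numeric.columns if numeric[c].isna().any()]
    bad = [c for c in cohort.columns if c in protected and cohort[c].isna().any()]
    if bad:
        raise ValueError(f"missing values in protected column(s) {bad}; only covariables may be imputed")
    for c in na_cols:
        if numeric[c].notna().sum() < min_observed:
            raise ValueError(f"column {c!r} has fewer than {min_observed} observed values")

    if not na_cols:
        return ImputationSet(
            m=m,
            completed_tables=[cohort.copy() for _ in range(m)],
            imputed_columns=(),
            seed=seed,
            n_cycles=n_cycles,
        )

    predictors = [
        c for c in numeric.columns
        if c not in ("subject_id",) and c not in na_cols
    ]
    # impute in increasing order of missingness (standard MICE visit order)
    na_cols = sorted(na_cols, key=lambda c: numeric[c].isna().sum())

    tables: list[pd.DataFrame] = []
    ss = np.random.SeedSequence(seed)
    for imp, child in enumerate(ss.spawn(m)):
        rng = np.random.default_rng(child)
        work = cohort.copy()
        # initial fill: observed mean
        for c in na_cols:
            work[c] = work[c].astype(float)
            work.loc[work[c].isna(), c] = cohort[c].mean()

        for _ in range(n_cycles):
            for c in na_cols:
                miss = cohort[c].isna().to_numpy()
                others = [o for o in na_cols if o != c]
                Xcols = predictors + others
                X = work[Xcols].to_numpy(dtype=float)
                # scale predictors for optimizer conditioning (no effect on
                # linear predictions, stabilizes the logistic fits)
                mu, sd = X.mean(axis=0), X.std(axis=0)
                sd[sd == 0] = 1.0
                X = (X - mu) / sd
                y_obs = cohort.loc[~miss, c].to_numpy(dtype=float)
                X_obs, X_mis = X[~miss], X[miss]
                if _is_binary(cohort[c]):
                    if len(np.unique(y_obs)) < 2:
                        work.loc[miss, c] = y_obs[0]
                        continue
                    model = LogisticRegression(max_iter=500)
                    model.fit(X_obs, y_obs)
                    p = model.predict_proba(X_mis)[:, 1]
                    work.loc[miss, c] = rng.binomial(1, p).astype(float)
                else:
                    model = LinearRegression()
                    model.fit(X_obs, y_obs)
                    resid = y_obs - model.predict(X_obs)
                    sd = float(np.std(resid, ddof=min(len(resid) - 1, X.shape[1] + 1)))
                    mu = model.predict(X_mis)
                    work.loc[miss, c] = mu + rng.normal(0.0, sd, size=len(mu))
        tables.append(work)

    return ImputationSet(
        m=m,
        completed_tables=tables,
        imputed_columns=tuple(na_cols),
        seed=seed,
        n_cycles=n_cycles,
    )


def age_equivalent(beta_exposure: float, beta_age: float) -> float:
    """Exposure effect expressed as months of age-related cognitive change.

    Divides the exposure coefficient by the per-year age coefficient from
    the same outcome model and converts years to months.
    """
    if beta_age == 0:
        raise ValueError("beta_age must be nonzero")
    return 12.0 * beta_exposure / beta_age
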