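"""End-to-end study orchestration.

Runs preprocessing, the 4-mediators x 2-outcomes single-mediator mediation
grid, the configured multiple-mediator sets, and the sensitivity variants;
collects everything into a :class:`ResultsTable` with an exclusion ledger
and deterministic report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mediation, multimediation
from .preprocess import (
    COGNITIVE_TESTS,
    compute_g_factor,
    dichotomize_microbleeds,
    impute_covariables,
    ln_transform_wmh,
    zscore,
)

__all__ = ["StudyConfig", "CellResult", "ResultsTable", "run_primary",
           "run_sensitivity", "render_report", "SENSITIVITY_VARIANTS"]


SENSITIVITY_VARIANTS = (
    "age_gt75",
    "ad_only",
    "no_cortical_infarct",
    "followup_3", "followup_5", "followup_10", "followup_15",
    "sex_male", "sex_female",
    "g_without_ppb",
    "lobar_mb",
)


@dataclass
class StudyConfig:
    exposure: str = "apoe4"
    confounders: tuple[str, ...] = (
        "age", "sex", "education", "smoking", "bmi", "sbp", "bp_med",
        "nonhdl", "lipid_med", "diabetes", "af", "stroke",
    )
    # mediator name -> (analysis column, type); ICV adjustment applies to the
    # volumetric/thickness markers only
    mediators: dict[str, dict] = field(default_factory=lambda: {
        "hv": {"column": "hv_z", "kind": "continuous", "icv": True},
        "ct_ad": {"column": "ct_ad_z", "kind": "continuous", "icv": True},
        "wmh": {"column": "wmh_z", "kind": "continuous", "icv": True},
        "mb2": {"column": "mb2", "kind": "binary", "icv": False},
    })
    outcomes: dict[str, str] = field(default_factory=lambda: {
        "g": "continuous", "dementia": "binary",
    })
    multi_sets: tuple[tuple[str, ...], ...] = (
        ("hv", "wmh"), ("hv", "mb2"), ("wmh", "mb2"),
        ("hv", "wmh", "mb2"), ("hv", "wmh", "mb2", "ct_ad"),
    )
    sensitivity: tuple[str, ...] = SENSITIVITY_VARIANTS
    boot_B: int = 1000
    m_imputations: int = 5
    mc_draws: int = 5
    seed: int = 0
    min_stratum_n: int = 100
    min_events: int = 10
    allow_common_outcome: bool = False

    def validate(self) -> None:
        for name, spec in self.mediators.items():
            if spec.get("icv") and name not in ("hv", "ct_ad", "wmh"):
                raise ValueError(f"icv adjustment is restricted to volumetric markers, not {name!r}")
        for v in self.sensitivity:
            if v not in SENSITIVITY_VARIANTS:
                raise ValueError(f"unknown sensitivity variant {v!r}")


@dataclass
class CellResult:
    outcome: str
    mediator_set: tuple[str, ...]
    variant: str
    status: str  # "ok" | "failed" | "underpowered"
    n: int = 0
    n_events: int | None = None
    scale: str = ""
    te: mediation.BootstrapSummary | None = None
    nde: mediation.BootstrapSummary | None = None
    nie: mediation.BootstrapSummary | None = None
    pm: mediation.BootstrapSummary | None = None
    message: str = ""

    def key(self) -> str:
        return f"{self.variant}|{self.outcome}|{'+'.join(self.mediator_set)}"


@dataclass
class ResultsTable:
    cells: list[CellResult] = field(default_factory=list)
    exclusions: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "variant": c.variant, "outcome": c.outcome,
                "mediators": "+".join(c.mediator_set), "status": c.status,
                "n": c.n, "n_events": c.n_events, "scale": c.scale,
                "message": c.message,
            }
            for name in ("te", "nde", "nie", "pm"):
                s = getattr(c, name)
                if s is not None:
                    row[f"{name}"] = s.point
                    row[f"{name}_ci_low"] = s.ci_low
                    row[f"{name}_ci_high"] = s.ci_high
                    row[f"{name}_p"] = s.p_value
            if c.pm is not None and np.isfinite(c.pm.point):
                row["pm_percent"] = round(100.0 * c.pm.point)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {"cells": {}, "exclusions": self.exclusions, "metadata": self.metadata}
        for c in self.cells:
            entry: dict = {
                "status": c.status, "n": c.n, "n_events": c.n_events,
                "scale": c.scale, "message": c.message,
            }
            for name in ("te", "nde", "nie", "pm"):
                s = getattr(c, name)
                entry[name] = s.to_dict() if s is not None else None
            if c.pm is not None and np.isfinite(c.pm.point):
                entry["pm_percent"] = round(100.0 * c.pm.point)
                entry["pm_raw"] = c.pm.point
            out["cells"][c.key()] = entry
        return out


def _derive_seed(seed: int, *labels) -> int:
    h = hashlib.sha256(("|".join(str(x) for x in labels)).encode()).digest()
    return (seed * 0x9E3779B1 + int.from_bytes(h[:4], "big")) % (2**31)


def _config_hash(config: StudyConfig) -> str:
    d = dataclasses.asdict(config)
    d["mediators"] = {k: dict(v) for k, v in d["mediators"].items()}
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# preprocessing


def prepare_cohort(cohort: pd.DataFrame, config: StudyConfig,
                   lobar: bool = False, include_ppb: bool = True) -> tuple[pd.DataFrame, dict]:
    """Derive analysis columns: standardized markers, mb2, g-factor.

    Returns the augmented table and an exclusion ledger.  The g-factor is
    computed on (and only assigned to) rows with a complete cognitive
    assessment; other rows carry NaN in ``g`` and are excluded from
    cognition analyses downstream.
    """
    out = cohort.copy()
    ledger: dict = {"n_input": int(len(out))}

    out["wmh_ln"] = ln_transform_wmh(out["wmh"])
    out["wmh_z"] = zscore(out["wmh_ln"])
    out["hv_z"] = zscore(out["hv"])
    out["ct_ad_z"] = zscore(out["ct_ad"])
    mb_source = "mb_lobar_count" if lobar else "mb_count"
    out["mb2"] = dichotomize_microbleeds(out[mb_source])

    tests = [t for t in COGNITIVE_TESTS if t in out.columns]
    if tests:
        complete = out[tests].notna().all(axis=1)
        ledger["excluded_incomplete_cognition"] = int((~complete).sum())
        gres = compute_g_factor(out.loc[complete, tests], include_ppb=include_ppb)
        out["g"] = np.nan
        out.loc[complete, "g"] = gres.scores
        ledger["n_cognition_sample"] = int(complete.sum())
    return out, ledger


# ---------------------------------------------------------------------------
# cells


def _run_cell(
    data: pd.DataFrame,
    outcome: str,
    outcome_kind: str,
    mediator_set: tuple[str, ...],
    config: StudyConfig,
    variant: str,
) -> CellResult:
    """One (outcome, mediator-set) analysis on one completed table."""
    med_cols = [config.mediators[m]["column"] for m in mediator_set]
    confs = list(config.confounders)
    if any(config.mediators[m].get("icv") for m in mediator_set):
        confs.append("icv")

    cols = [outcome, config.exposure, *med_cols, *confs]
    sub = data[cols].dropna()
    n = len(sub)
    n_events = int(sub[outcome].sum()) if outcome_kind == "binary" else None

    cell = CellResult(outcome=outcome, mediator_set=mediator_set, variant=variant,
                      status="ok", n=n, n_events=n_events)
    if n < config.min_stratum_n or (n_events is not None and n_events < config.min_events):
        cell.status = "underpowered"
        cell.message = f"n={n}, events={n_events}: below configured minimum"
        return cell

    seed = _derive_seed(config.seed, variant, outcome, *mediator_set)
    out_link = "logit" if outcome_kind == "binary" else "identity"
    try:
        if len(mediator_set) == 1:
            mspec = config.mediators[mediator_set[0]]
            res = mediation.run_single_mediation(
                sub, outcome, config.exposure, mspec["column"], confs,
                outcome_link=out_link,
                mediator_link="logit" if mspec["kind"] == "binary" else "identity",
                B=config.boot_B, seed=seed,
                allow_common_outcome=config.allow_common_outcome,
            )
            cell.scale = res["decomposition"].scale
            cell.te, cell.nde, cell.nie, cell.pm = res["te"], res["nde"], res["nie"], res["pm"]
        else:
            links = {
                config.mediators[m]["column"]:
                    "logit" if config.mediators[m]["kind"] == "binary" else "identity"
                for m in mediator_set
            }
            # variant-independent so identical data gives identical estimates
            mc_seed = _derive_seed(config.seed, "mc", outcome, *mediator_set)

            def decompose(d: pd.DataFrame) -> multimediation.JointEffectDecomposition:
                jf = multimediation.fit_joint(
                    d, outcome, config.exposure, med_cols, confs,
                    outcome_link=out_link, mediator_links=links,
                )
                return multimediation.joint_natural_effects(
                    jf, d, mc_draws=config.mc_draws, seed=mc_seed
                )

            dec = decompose(sub)
            vec = lambda d: (lambda x: np.array([x.te, x.nde, x.nie, x.pm]))(decompose(d))
            draws, failed = mediation._bootstrap_draws(vec, sub, 4, config.boot_B, seed)
            log_scale = dec.scale == "odds-ratio"
            cell.scale = dec.scale
            for j, name in enumerate(("te", "nde", "nie")):
                setattr(cell, name, mediation._percentile_summary(
                    getattr(dec, name), draws[:, j], config.boot_B, seed,
                    estimand=f"{outcome}|{'+'.join(mediator_set)}|{name}",
                    log_scale=log_scale, n_failed=failed,
                ))
            pm_s = mediation._percentile_summary(
                dec.pm, draws[:, 3], config.boot_B, seed,
                estimand=f"{outcome}|{'+'.join(mediator_set)}|pm", n_failed=failed,
            )
            pm_s.p_value = cell.nie.p_value
            cell.pm = pm_s
    except Exception as exc:  # record, keep going
        cell.status = "failed"
        cell.message = f"{type(exc).__name__}: {exc}"
    return cell


def _pool_cells(cells: list[CellResult]) -> CellResult:
    """Pool one cell estimated on each of m imputed tables."""
    ok = [c for c in cells if c.status == "ok"]
    if not ok:
        return cells[0]
    base = ok[0]
    pooled = CellResult(
        outcome=base.outcome, mediator_set=base.mediator_set, variant=base.variant,
        status="ok", n=base.n, n_events=base.n_events, scale=base.scale,
    )
    for name in ("te", "nde", "nie", "pm"):
        pooled_s = mediation.pool_imputations([getattr(c, name) for c in ok])
        setattr(pooled, name, pooled_s)
    pooled.pm.p_value = pooled.nie.p_value
    return pooled


def _apply_variant(prepared: pd.DataFrame, variant: str) -> tuple[pd.DataFrame, set[str] | None, list[str] | None]:
    """Return (data, restricted outcome set or None, restricted mediator list or None)."""
    d = prepared
    if variant == "primary":
        return d, None, None
    if variant == "age_gt75":
        return d[d["age"] > 75], {"dementia"}, None
    if variant == "ad_only":
        d = d.copy()
        d["dementia"] = ((d["dementia"] == 1) & (d["dementia_subtype"] == "AD")).astype(int)
        return d, {"dementia"}, None
    if variant == "no_cortical_infarct":
        return d[d["cortical_infarct"] == 0], None, ["wmh", "mb2"]
    if variant.startswith("followup_"):
        horizon = float(variant.split("_")[1])
        d = d.copy()
        d["dementia"] = ((d["dementia"] == 1) & (d["dementia_time"] <= horizon)).astype(int)
        return d, {"dementia"}, None
    if variant == "sex_male":
        return d[d["sex"] == 0], None, None
    if variant == "sex_female":
        return d[d["sex"] == 1], None, None
    raise ValueError(f"unknown sensitivity variant {variant!r}")


def _run_grid(
    tables: list[pd.DataFrame],
    config: StudyConfig,
    variant: str,
    outcomes: set[str] | None = None,
    mediators: list[str] | None = None,
    include_multi: bool = True,
) -> list[CellResult]:
    cells: list[CellResult] = []
    med_names = mediators if mediators is not None else list(config.mediators)
    for outcome, kind in config.outcomes.items():
        if outcomes is not None and outcome not in outcomes:
            continue
        sets: list[tuple[str, ...]] = [(m,) for m in med_names]
        if include_multi:
            sets += [s for s in config.multi_sets if all(m in med_names for m in s)]
        for mediator_set in sets:
            per_imp = [
                _run_cell(t, outcome, kind, tuple(mediator_set), config, variant)
                for t in tables
            ]
            cells.append(_pool_cells(per_imp) if len(per_imp) > 1 else per_imp[0])
    return cells


# ---------------------------------------------------------------------------
# public operations


def run_primary(cohort: pd.DataFrame, config: StudyConfig | None = None) -> ResultsTable:
    """Preprocess, impute, and run the full primary mediation grid."""
    config = config or StudyConfig()
    config.validate()
    prepared, ledger = prepare_cohort(cohort, config)
    imps = impute_covariables(prepared, m=config.m_imputations, seed=config.seed)
    ledger["imputed_columns"] = list(imps.imputed_columns)
    tables = imps.completed_tables if imps.imputed_columns else [prepared]

    cells = _run_grid(tables, config, "primary")
    meta = {
        "seed": config.seed, "boot_B": config.boot_B,
        "m_imputations": len(tables), "config_hash": _config_hash(config),
        "multiple_testing_adjustment": "none",
    }
    if config.boot_B < 100:
        meta["warning"] = f"boot_B={config.boot_B}: confidence intervals are low-precision"
    return ResultsTable(cells=cells, exclusions=ledger, metadata=meta)


def run_sensitivity(cohort: pd.DataFrame, config: StudyConfig | None, variant: str) -> ResultsTable:
    """Run the mediation grid for one sensitivity variant."""
    config = config or StudyConfig()
    config.validate()
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown sensitivity variant {variant!r}")

    lobar = variant == "lobar_mb"
    include_ppb = variant != "g_without_ppb"
    prepared, ledger = prepare_cohort(cohort, config, lobar=lobar, include_ppb=include_ppb)

    if variant in ("lobar_mb", "g_without_ppb"):
        data, outcomes, meds = prepared, None, None
        if variant == "lobar_mb":
            meds = ["mb2"]
        if variant == "g_without_ppb":
            outcomes = {"g"}
    else:
        data, outcomes, meds = _apply_variant(prepared, variant)
    ledger["n_variant_sample"] = int(len(data))

    imps = impute_covariables(data, m=config.m_imputations, seed=config.seed)
    tables = imps.completed_tables if imps.imputed_columns else [data]
    cells = _run_grid(tables, config, variant, outcomes=outcomes, mediators=meds)
    meta = {"seed": config.seed, "variant": variant, "config_hash": _config_hash(config)}
    return ResultsTable(cells=cells, exclusions=ledger, metadata=meta)


def render_report(results: ResultsTable, out_dir: str | Path) -> dict[str, Path]:
    """Write results.csv / results.json / exclusions.json / run.log.

    Output is deterministic (no timestamps; sorted keys), so identical
    seed + config reruns are byte-identical.
    """
    if not results.cells:
        raise ValueError("render_report: results table is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": out / "results.csv",
        "json": out / "results.json",
        "exclusions": out / "exclusions.json",
        "log": out / "run.log",
    }
    results.to_frame().to_csv(paths["csv"], index=False)
    paths["json"].write_text(json.dumps(results.to_dict(), sort_keys=True, indent=1) + "\n")
    paths["exclusions"].write_text(json.dumps(results.exclusions, sort_keys=True, indent=1) + "\n")
    lines = [f"{k}={v}" for k, v in sorted(results.metadata.items())]
    n_failed = sum(1 for c in results.cells if c.status != "ok")
    lines.append(f"cells={len(results.cells)} non_ok={n_failed}")
    for c in results.cells:
        if c.status != "ok":
            lines.append(f"cell {c.key()}: {c.status} ({c.message})")
    paths["log"].write_text("\n".join(lines) + "\n")
    return paths
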