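"""Readers/writers for the cohort CSV tables, YAML configs and fit reports.

Table contract (comma-separated, UTF-8, header row mandatory, times in
decimal months):

* ``baseline.csv`` — one row per subject: id, categorical covariates
  (sex, residence, regimen, drug_type), 0/1 comorbidity indicators and
  continuous labs;
* ``longitudinal.csv`` — id, time_months, sbp_mmhg, dbp_mmhg;
* ``survival.csv`` — id, time_months, event (0/1).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .errors import SchemaError
from .inference import PosteriorChains, hazard_ratio_summary
from .params import DesignSpec
from .simulate import CohortConfig

LONG_COLUMNS = ("id", "time_months", "sbp_mmhg", "dbp_mmhg")
SURV_COLUMNS = ("id", "time_months", "event")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_tables(baseline_path, long_path, surv_path):
    """Read and cross-validate the three cohort tables.

    Checks: required columns, numeric types, id consistency across the
    tables, non-negative times, no duplicate (id, time) visit rows, and
    longitudinal visits not after the subject's exit time.  Errors name
    the offending ids/rows.
    """
    baseline = pd.read_csv(baseline_path)
    long_table = pd.read_csv(long_path)
    survival = pd.read_csv(surv_path)
    _require_columns(baseline, ("id",), baseline_path)
    _require_columns(long_table, LONG_COLUMNS, long_path)
    _require_columns(survival, SURV_COLUMNS, surv_path)
    for col in LONG_COLUMNS[1:]:
        long_table[col] = pd.to_numeric(long_table[col], errors="raise")
    for col in SURV_COLUMNS[1:]:
        survival[col] = pd.to_numeric(survival[col], errors="raise")

    if baseline["id"].duplicated().any():
        dup = baseline.loc[baseline["id"].duplicated(), "id"].tolist()
        raise SchemaError(f"duplicate subject ids in baseline table: {dup}")
    base_ids = set(baseline["id"])
    for name, df in (("longitudinal", long_table), ("survival", survival)):
        orphans = sorted(set(df["id"]) - base_ids)
        if orphans:
            raise SchemaError(f"{name} table has ids absent from baseline: {orphans}")
    missing_surv = sorted(base_ids - set(survival["id"]))
    if missing_surv:
        raise SchemaError(f"subjects without survival record: {missing_surv}")
    long_only = sorted(set(long_table["id"]) - set(survival["id"]))
    if long_only:
        raise SchemaError(
            f"ids present in longitudinal but absent in survival: {long_only}"
        )

    neg = long_table.index[long_table["time_months"] < 0].tolist()
    if neg or (survival["time_months"] < 0).any():
        raise SchemaError(f"negative times (longitudinal rows {neg})")
    if not survival["event"].isin((0, 1)).all():
        raise SchemaError("event indicator must be 0 or 1")
    dups = long_table.duplicated(subset=["id", "time_months"])
    if dups.any():
        raise SchemaError(
            f"duplicate (id, time) longitudinal rows: {long_table.index[dups].tolist()}"
        )
    exit_time = survival.set_index("id")["time_months"]
    late = long_table["time_months"].to_numpy() > exit_time.loc[
        long_table["id"]
    ].to_numpy() + 1e-9
    if late.any():
        raise SchemaError(
            f"longitudinal visits after exit for rows {long_table.index[late].tolist()}"
        )
    return baseline, long_table, survival


def load_config(path) -> dict:
    """Load a YAML run configuration; returns {} for an absent path."""
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def cohort_config_from_yaml(cfg: dict) -> CohortConfig:
    kw = {}
    sim = cfg.get("simulate", cfg)
    for key in (
        "n_subjects",
        "visit_schedule",
        "admin_censor_time",
        "covariate_frequencies",
        "covariate_moments",
        "dropout_rate",
        "seed",
    ):
        if key in sim:
            kw[key] = sim[key]
    if "visit_schedule" in kw:
        kw["visit_schedule"] = tuple(float(t) for t in kw["visit_schedule"])
    if "covariate_moments" in kw:
        kw["covariate_moments"] = {
            k: tuple(v) for k, v in kw["covariate_moments"].items()
        }
    return CohortConfig(**kw)


def design_from_yaml(cfg: dict) -> DesignSpec:
    d = cfg.get("design", {})
    return DesignSpec(
        sbp_covariates=tuple(d.get("sbp_covariates", defaults.SBP_COVARIATES)),
        dbp_covariates=tuple(d.get("dbp_covariates", defaults.DBP_COVARIATES)),
        survival_covariates=tuple(
            d.get("survival_covariates", defaults.SURVIVAL_COVARIATES)
        ),
    )


def write_report(chains: PosteriorChains, out_dir, descriptives=None) -> dict:
    """Write summary.csv, chains.npz, diagnostics.json and report.json.

    ``summary.csv`` has one row per parameter (posterior mean, SE,
    central 95% interval, R-hat, ESS); the hazard-ratio section of
    ``report.json`` exp-transforms the survival coefficients.
    Returns the report dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = chains.summary()
    summary.to_csv(out / "summary.csv")
    display = summary.round(4)
    display.to_csv(out / "summary_display.csv")
    np.savez_compressed(out / "chains.npz", **{k: v for k, v in chains.draws.items()})
    diagnostics = {
        "rhat_max": float(summary["rhat"].max()),
        "converged": bool(summary.attrs.get("converged", False)),
        "ess_min": float(summary["ess"].min()),
        "acceptance": chains.acceptance,
        "knots": chains.knots.tolist(),
        "n_chains": chains.config.n_chains,
        "n_iter": chains.config.n_iter,
        "burn_in": chains.config.burn_in,
        "thin": chains.config.thin,
        "seed": chains.config.seed,
    }
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    hr = {}
    for group in ("gamma", "rho"):
        for label in chains.param_names.get(group, []):
            hr[label] = hazard_ratio_summary(chains.flat(label))
    report = {
        "parameters": json.loads(summary.reset_index().to_json(orient="records")),
        "hazard_ratios": hr,
        "diagnostics": diagnostics,
    }
    if descriptives is not None:
        report["descriptives"] = descriptives
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
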