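"""Synthetic cohort generator.

Emulates a registry-style hypertension cohort: baseline covariates drawn
from the study's observed margins, bivariate SBP/DBP trajectories from
the mixed sub-model, and first-remission times from the linked
proportional-hazards sub-model by inverse-transform sampling, with
administrative censoring at the end of the follow-up window.  Visits stop
at a subject's exit (event or censoring), as in the source registry.

Event times come from the hazard model itself rather than from observed
threshold crossings, so that downstream parameter-recovery experiments
test exactly the model being fitted; a threshold-based remission flag
(first visit with observed SBP < 140 and DBP < 90) is available as a
separate diagnostic.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import defaults
from .design import covariate_matrix
from .errors import ConfigurationError
from .longitudinal import marker_mean
from .params import DesignSpec, TruthParams
from .survival import invert_cumulative_hazard, trajectory_coefficients


@dataclass
class CohortConfig:
    """Study-design quantities of the synthetic cohort.

    Defaults are the source study's conditions: n = 301 outpatients,
    monthly visits starting at enrolment (t = 0), administrative
    censoring at 30 months, and baseline covariate margins from the
    observed cohort.  ``covariate_moments`` maps each continuous
    covariate to (mean, SD, lower, upper) of a truncated normal; the age
    lower bound of 15 years mirrors the inclusion criteria.
    """

    n_subjects: int = defaults.N_SUBJECTS
    visit_schedule: tuple[float, ...] = defaults.VISIT_SCHEDULE
    admin_censor_time: float = defaults.FOLLOW_UP_MONTHS
    covariate_frequencies: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.COVARIATE_FREQUENCIES.items()}
    )
    covariate_moments: dict = field(
        default_factory=lambda: dict(defaults.COVARIATE_MOMENTS)
    )
    dropout_rate: float = 0.0  # optional exponential dropout, events/month
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be non-negative")
        sched = np.asarray(self.visit_schedule, dtype=float)
        if sched.size == 0:
            raise ConfigurationError("visit schedule must be non-empty")
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ConfigurationError("visit schedule must start at 0 and strictly increase")
        if self.admin_censor_time < sched[-1]:
            raise ConfigurationError("admin censor time must not precede the last visit")
        for cov, freqs in self.covariate_frequencies.items():
            probs = np.array(list(freqs.values()), dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"category probabilities for covariate {cov!r} must be "
                    f"non-negative and sum to 1 (got sum {probs.sum()!r})"
                )
        if self.dropout_rate < 0:
            raise ConfigurationError("dropout rate must be non-negative")


def sample_baseline(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the baseline covariate table (one row per subject)."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_subjects
    data: dict[str, np.ndarray] = {"id": np.arange(1, n + 1)}
    for cov, freqs in config.covariate_frequencies.items():
        cats = list(freqs)
        probs = np.array([freqs[c] for c in cats], dtype=float)
        draws = rng.choice(len(cats), size=n, p=probs)
        if cov in ("dm", "ckd", "stroke", "hiv"):
            yes = np.array([c == "yes" for c in cats])
            data[cov] = yes[draws].astype(int)
        else:
            data[cov] = np.array(cats, dtype=object)[draws]
    for cov, (mean, sd, lo, hi) in config.covariate_moments.items():
        a, b = (lo - mean) / sd, (hi - mean) / sd
        data[cov] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return pd.DataFrame(data)


def sample_random_effects(
    n: int, covariance: np.ndarray, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Zero-mean multivariate-normal subject effects (a1, b1, a2, b2)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cov = np.asarray(covariance, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ConfigurationError("random-effect covariance must be symmetric")
    if np.allclose(cov, 0):
        return np.zeros((n, cov.shape[0]))
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("random-effect covariance is not positive definite") from exc
    return rng.standard_normal((n, cov.shape[0])) @ chol.T


def sample_trajectories(
    cohort: pd.DataFrame,
    effects: np.ndarray,
    truth: TruthParams,
    schedule,
    spec: DesignSpec | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Observed and true marker values at every scheduled visit.

    Returns ``(observed, true)`` long tables with columns
    (id, time_months, sbp_mmhg, dbp_mmhg); the true table is noise-free
    and intended for oracle checks.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ConfigurationError("visit schedule must be non-empty")
    spec = spec or defaults.default_design()
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    if len(effects) != len(cohort):
        raise ConfigurationError("need one random-effect vector per subject")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    u1 = covariate_matrix(cohort, spec.sbp_covariates)
    u2 = covariate_matrix(cohort, spec.dbp_covariates)
    n, k = len(cohort), schedule.size
    ids = np.repeat(cohort["id"].to_numpy(), k)
    times = np.tile(schedule, n)
    m1, m2 = marker_mean(
        truth.lmm,
        np.repeat(effects, k, axis=0),
        np.repeat(u1, k, axis=0),
        np.repeat(u2, k, axis=0),
        times,
    )
    s1, s2 = truth.lmm.sigma_eps
    y1 = m1 + s1 * rng.standard_normal(n * k)
    y2 = m2 + s2 * rng.standard_normal(n * k)
    obs = pd.DataFrame({"id": ids, "time_months": times, "sbp_mmhg": y1, "dbp_mmhg": y2})
    true = pd.DataFrame({"id": ids, "time_months": times, "sbp_mmhg": m1, "dbp_mmhg": m2})
    return obs, true


def sample_event_time(
    traj_row, u_surv_row, truth: TruthParams, u: float, admin_censor_time: float
):
    """Inverse-transform draw of one first-remission time.

    Solves Lambda_i(T) = -log(u) by bracketed root finding; if the
    cumulative hazard never reaches the target within the follow-up
    window the subject is administratively censored.
    Returns (time, event_indicator).
    """
    if not 0.0 < u < 1.0:
        raise ConfigurationError("uniform draw must lie strictly in (0, 1)")
    target = -float(np.log(u))
    t = invert_cumulative_hazard(target, traj_row, u_surv_row, truth.hazard, admin_censor_time)
    if t is None:
        return float(admin_censor_time), 0
    return t, 1


def threshold_remission_times(long_table: pd.DataFrame) -> pd.Series:
    """Diagnostic: first visit with observed SBP < 140 and DBP < 90 per id."""
    controlled = long_table[
        (long_table["sbp_mmhg"] < 140.0) & (long_table["dbp_mmhg"] < 90.0)
    ]
    return controlled.groupby("id")["time_months"].min()


def generate_cohort(
    config: CohortConfig | None = None,
    truth: TruthParams | None = None,
    seed: int | None = None,
    spec: DesignSpec | None = None,
):
    """Full synthetic data set: baseline, longitudinal and survival tables.

    Deterministic for a fixed seed.  Longitudinal rows after a subject's
    event/censoring time are dropped (visits stop at exit).  Returns
    ``(cohort, longitudinal, survival, truth)``.
    """
    config = config or CohortConfig()
    truth = truth or defaults.default_truth(spec)
    spec = spec or defaults.default_design()
    config.validate()
    truth.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    cohort = sample_baseline(config, rng)
    effects = sample_random_effects(config.n_subjects, truth.lmm.Sigma, rng)
    obs, true = sample_trajectories(cohort, effects, truth, config.visit_schedule, spec, rng)

    u1 = covariate_matrix(cohort, spec.sbp_covariates)
    u2 = covariate_matrix(cohort, spec.dbp_covariates)
    us = covariate_matrix(cohort, spec.survival_covariates)
    traj = trajectory_coefficients(truth.lmm, effects, u1, u2)

    uniforms = rng.uniform(size=config.n_subjects)
    times = np.empty(config.n_subjects)
    events = np.empty(config.n_subjects, dtype=int)
    for i in range(config.n_subjects):
        times[i], events[i] = sample_event_time(
            traj[i], us[i], truth, uniforms[i], config.admin_censor_time
        )
    if config.dropout_rate > 0:
        drop = rng.exponential(1.0 / config.dropout_rate, size=config.n_subjects)
        dropped = drop < times
        times = np.where(dropped, drop, times)
        events = np.where(dropped, 0, events)

    survival = pd.DataFrame({"id": cohort["id"], "time_months": times, "event": events})
    exit_time = survival.set_index("id")["time_months"]
    keep = obs["time_months"].to_numpy() <= exit_time.loc[obs["id"]].to_numpy()
    longitudinal = obs.loc[keep].reset_index(drop=True)
    return cohort, longitudinal, survival, truth


def write_cohort(out_dir, cohort, longitudinal, survival, truth: TruthParams) -> None:
    """Write baseline/longitudinal/survival CSVs plus the generating truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "baseline.csv", index=False)
    longitudinal.to_csv(out / "longitudinal.csv", index=False)
    survival.to_csv(out / "survival.csv", index=False)
    record = {
        "beta_sbp": truth.lmm.beta_sbp.tolist(),
        "beta_dbp": truth.lmm.beta_dbp.tolist(),
        "delta_sbp": truth.lmm.delta_sbp.tolist(),
        "delta_dbp": truth.lmm.delta_dbp.tolist(),
        "Sigma": truth.lmm.Sigma.tolist(),
        "sigma_eps": truth.lmm.sigma_eps.tolist(),
        "log_baseline": truth.hazard.log_baseline.tolist(),
        "knots": truth.hazard.knots.tolist(),
        "gamma": truth.hazard.gamma.tolist(),
        "rho": truth.hazard.rho.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(record, indent=2))
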