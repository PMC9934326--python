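"""Proportional-hazards sub-model linked to the true marker trajectories,
plus classical Kaplan-Meier / log-rank descriptives.

The hazard of first remission for subject i is

    h_i(t) = h0(t) * exp( gamma' u_i + rho . (m1(t), m1'(t), m2(t), m2'(t)) )

with h0 piecewise constant between knots and (m1, m2) the true SBP/DBP
trajectories of the mixed sub-model ("current value and slope"
association).  Because each trajectory is linear in t, subjects are fully
described by intercepts/slopes (A1, B1, A2, B2): m_k(t) = A_k + B_k t.
Cumulative hazards are computed by fixed-order Gauss-Legendre quadrature
applied piecewise between knots, which is accurate to near machine
precision for these exponential-of-linear integrands.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.optimize import brentq

from .errors import ConfigurationError, NumericalError
from .params import HazardParams

#: quadrature order per knot interval
GAUSS_LEGENDRE_ORDER = 15


def trajectory_coefficients(lmm, effects, u_sbp, u_dbp) -> np.ndarray:
    """Per-subject (A1, B1, A2, B2) with m_k(t) = A_k + B_k t.

    Convenience bridge from the longitudinal sub-model: A is the
    trajectory value at t = 0, B its constant slope.
    """
    b = np.atleast_2d(np.asarray(effects, dtype=float))
    u1 = np.atleast_2d(np.asarray(u_sbp, dtype=float))
    u2 = np.atleast_2d(np.asarray(u_dbp, dtype=float))
    A1 = lmm.beta_sbp[0] + u1 @ lmm.delta_sbp + b[:, 0]
    B1 = lmm.beta_sbp[1] + b[:, 1]
    A2 = lmm.beta_dbp[0] + u2 @ lmm.delta_dbp + b[:, 2]
    B2 = lmm.beta_dbp[1] + b[:, 3]
    return np.column_stack([A1, B1, A2, B2])


def baseline_level_index(t, knots: np.ndarray) -> np.ndarray:
    """Index of the piecewise-constant interval containing each time.

    Times beyond the last knot use the last level.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("negative time in baseline hazard lookup")
    return np.clip(np.searchsorted(knots, t, side="right") - 1, 0, knots.size - 1)


def _traj(traj) -> np.ndarray:
    traj = np.asarray(traj, dtype=float)
    if traj.ndim == 1:
        traj = traj[None, :]
    if traj.shape[1] != 4:
        raise ConfigurationError("trajectory must be (A1, B1, A2, B2)")
    return traj


def log_hazard(t, traj, u_surv, params: HazardParams) -> np.ndarray:
    """Log instantaneous hazard at time(s) t for subject trajectory rows."""
    params.validate()
    traj = _traj(traj)
    u = np.atleast_2d(np.asarray(u_surv, dtype=float))
    t = np.asarray(t, dtype=float)
    lev = params.log_baseline[baseline_level_index(t, params.knots)]
    m1 = traj[:, 0] + traj[:, 1] * t
    m2 = traj[:, 2] + traj[:, 3] * t
    assoc = (
        params.rho[0] * m1
        + params.rho[1] * traj[:, 1]
        + params.rho[2] * m2
        + params.rho[3] * traj[:, 3]
    )
    return lev + u @ params.gamma + assoc


def hazard(t, traj, u_surv, params: HazardParams) -> np.ndarray:
    """Instantaneous hazard h_i(t); strictly positive."""
    return np.squeeze(np.exp(log_hazard(t, traj, u_surv, params)))


def cumulative_hazard(T, traj, u_surv, params: HazardParams) -> float | np.ndarray:
    """Integrated hazard Lambda_i(T) via piecewise Gauss-Legendre quadrature."""
    params.validate()
    traj = _traj(traj)
    u = np.atleast_2d(np.asarray(u_surv, dtype=float))
    scalar = np.isscalar(T) or np.ndim(T) == 0
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T < 0):
        raise ConfigurationError("negative survival time")
    nodes, weights = np.polynomial.legendre.leggauss(GAUSS_LEGENDRE_ORDER)
    out = np.zeros(T.size)
    for i, Ti in enumerate(T):
        row = traj[i if traj.shape[0] > 1 else 0]
        ui = u[i if u.shape[0] > 1 else 0]
        edges = np.concatenate([params.knots[params.knots < Ti], [Ti]])
        total = 0.0
        for a, bnd in zip(edges[:-1], edges[1:]):
            half = 0.5 * (bnd - a)
            tq = a + half * (nodes + 1.0)
            total += half * np.sum(weights * np.exp(log_hazard(tq, row, ui, params)))
        out[i] = total
    return float(out[0]) if scalar else out


def loglik_event(time, event, traj, u_surv, params: HazardParams) -> float:
    """Log-likelihood contribution d*log h(T) - Lambda(T) of one subject."""
    if time < 0:
        raise ConfigurationError("negative survival time")
    if event not in (0, 1):
        raise ConfigurationError("event indicator must be 0 or 1")
    lam = cumulative_hazard(float(time), traj, u_surv, params)
    if event:
        return float(np.squeeze(log_hazard(float(time), _traj(traj), u_surv, params))) - lam
    return -lam


def invert_cumulative_hazard(
    target: float, traj, u_surv, params: HazardParams, t_max: float
) -> float | None:
    """Solve Lambda(T) = target on (0, t_max]; None if not reached by t_max.

    Used by the simulator's inverse-transform sampling of event times.
    """
    if target <= 0:
        raise ConfigurationError("cumulative-hazard target must be positive")
    lam_max = cumulative_hazard(t_max, traj, u_surv, params)
    if lam_max < target:
        return None
    try:
        return float(
            brentq(
                lambda s: cumulative_hazard(s, traj, u_surv, params) - target,
                0.0,
                t_max,
                xtol=1e-10,
                maxiter=200,
            )
        )
    except (RuntimeError, ValueError) as exc:
        raise NumericalError(f"event-time root finding failed: {exc}") from exc


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    median: float  # NaN when not reached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate of the remission-free survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ConfigurationError("empty survival data")
    if np.any(times < 0):
        raise ConfigurationError("negative survival time")
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    table = fitter.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = fitter.survival_function_.iloc[:, 0].to_numpy()
    at_risk = table["at_risk"].to_numpy()
    median = float(fitter.median_survival_time_)
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0]),
        median=median if np.isfinite(median) else float("nan"),
    )


def logrank_test(times, events, groups):
    """Log-rank chi-square test across >= 2 groups.

    Returns (statistic, degrees of freedom, p-value).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ConfigurationError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)
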