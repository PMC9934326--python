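"""Bivariate linear mixed sub-model for SBP/DBP trajectories.

Each marker follows

    Y_ij(t) = m_i(t) + eps_ij,   eps_ij ~ N(0, sigma_eps^2)
    m_i(t)  = X(t)'beta + Z(t)'b_i + u_i'delta

with X(t) = Z(t) = (1, t), subject random effects
b_i = (a_i1, b_i1, a_i2, b_i2) ~ N(0, Sigma) shared across the two
markers, and independent measurement error.  Because time enters
linearly, the true trajectory of each marker is a subject-specific line;
its slope is the fixed time coefficient plus the random slope.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .design import covariate_matrix
from .errors import ConfigurationError, SchemaError
from .params import DesignSpec, LMMParams

_LOG_2PI = float(np.log(2.0 * np.pi))


def _effects_array(effects) -> np.ndarray:
    b = np.asarray(effects, dtype=float)
    if b.ndim == 1:
        b = b[None, :]
    if b.shape[1] != 4:
        raise ConfigurationError("random effects must have 4 columns (a1, b1, a2, b2)")
    return b


def marker_mean(params: LMMParams, effects, u_sbp, u_dbp, t):
    """True (noise-free) marker values m1(t), m2(t) in mmHg.

    ``effects`` is an (n, 4) array (or a single 4-vector), ``u_sbp`` /
    ``u_dbp`` the matching covariate rows, ``t`` a scalar or per-row array
    of times in months.  Returns a pair of arrays broadcast over subjects.
    """
    b = _effects_array(effects)
    u1 = np.atleast_2d(np.asarray(u_sbp, dtype=float))
    u2 = np.atleast_2d(np.asarray(u_dbp, dtype=float))
    if u1.shape[1] != params.delta_sbp.size or u2.shape[1] != params.delta_dbp.size:
        raise ConfigurationError("covariate row length does not match delta")
    t = np.asarray(t, dtype=float)
    m1 = params.beta_sbp[0] + u1 @ params.delta_sbp + b[:, 0] + (params.beta_sbp[1] + b[:, 1]) * t
    m2 = params.beta_dbp[0] + u2 @ params.delta_dbp + b[:, 2] + (params.beta_dbp[1] + b[:, 3]) * t
    return np.squeeze(m1), np.squeeze(m2)


def marker_slope(params: LMMParams, effects):
    """Trajectory slopes (dm1/dt, dm2/dt) in mmHg/month; constant in t."""
    b = _effects_array(effects)
    return (
        np.squeeze(params.beta_sbp[1] + b[:, 1]),
        np.squeeze(params.beta_dbp[1] + b[:, 3]),
    )


def marginal_covariance(params: LMMParams, t: float):
    """Marginal 2x2 covariance and correlation of observed (SBP, DBP) at t.

    Integrating the random effects out of the mixed model gives, with
    w = (1, t) and Sigma partitioned into 2x2 blocks per marker,

        var(Y1) = w' Sigma_11 w + sigma1^2
        var(Y2) = w' Sigma_22 w + sigma2^2
        cov(Y1, Y2) = w' Sigma_12 w

    (the measurement errors of the two markers are independent, so only
    the shared random effects correlate them).
    """
    if t < 0:
        raise ConfigurationError("time must be non-negative")
    params.validate()
    w = np.array([1.0, float(t)])
    S = params.Sigma
    v1 = w @ S[:2, :2] @ w + params.sigma_eps[0] ** 2
    v2 = w @ S[2:, 2:] @ w + params.sigma_eps[1] ** 2
    c = w @ S[:2, 2:] @ w
    cov = np.array([[v1, c], [c, v2]])
    denom = np.sqrt(v1 * v2)
    corr = 0.0 if denom == 0 else float(c / denom)
    return cov, corr


def loglik_longitudinal(
    params: LMMParams,
    effects,
    long_table: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: DesignSpec,
) -> float:
    """Gaussian log-likelihood of a long-format (id, time, sbp, dbp) table.

    ``effects`` holds one 4-vector per cohort row, aligned with
    ``cohort``'s order; measurements are conditionally independent given
    the effects, so the result is a plain sum of normal log-densities.
    """
    if np.any(params.sigma_eps <= 0):
        raise ConfigurationError("residual SDs must be strictly positive")
    b = _effects_array(effects)
    if len(b) != len(cohort):
        raise ConfigurationError("need one random-effect vector per subject")
    ids = cohort["id"].to_numpy()
    pos = {i: k for k, i in enumerate(ids)}
    try:
        idx = np.array([pos[i] for i in long_table["id"]], dtype=int)
    except KeyError as exc:
        raise SchemaError(f"longitudinal id {exc.args[0]!r} absent from baseline table") from None
    u1 = covariate_matrix(cohort, spec.sbp_covariates)
    u2 = covariate_matrix(cohort, spec.dbp_covariates)
    t = long_table["time_months"].to_numpy(dtype=float)
    m1 = (
        params.beta_sbp[0]
        + (u1 @ params.delta_sbp)[idx]
        + b[idx, 0]
        + (params.beta_sbp[1] + b[idx, 1]) * t
    )
    m2 = (
        params.beta_dbp[0]
        + (u2 @ params.delta_dbp)[idx]
        + b[idx, 2]
        + (params.beta_dbp[1] + b[idx, 3]) * t
    )
    r1 = long_table["sbp_mmhg"].to_numpy(dtype=float) - m1
    r2 = long_table["dbp_mmhg"].to_numpy(dtype=float) - m2
    s1, s2 = params.sigma_eps
    n = r1.size
    ll = -0.5 * (
        2 * n * _LOG_2PI
        + 2 * n * np.log(s1 * s2)
        + np.sum(r1**2) / s1**2
        + np.sum(r2**2) / s2**2
    )
    return float(ll)
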