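"""Parameter containers for the joint blood-pressure / remission model.

The model has three parameter groups:

* ``LMMParams`` — the bivariate linear mixed sub-model for systolic and
  diastolic blood pressure (SBP/DBP, mmHg): per-marker fixed effects on
  (intercept, time) and on time-invariant baseline covariates, a shared
  4x4 random-effect covariance for (random intercept, random slope) of
  each marker, and the two residual standard deviations.
* ``HazardParams`` — the proportional-hazards sub-model for time to first
  remission: piecewise-constant baseline hazard, log hazard ratios for
  baseline covariates, and a length-4 association vector linking the
  hazard to the current value and current slope of each marker.
* ``ShrinkageHyper`` — the global-local ridge hyper-parameters of the
  shrinkage prior on the association vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: order of the subject-level random effects b_i
RANDOM_EFFECTS = ("sbp_intercept", "sbp_slope", "dbp_intercept", "dbp_slope")
#: order of the association vector rho
ASSOCIATION_TERMS = ("value_sbp", "slope_sbp", "value_dbp", "slope_dbp")


def covariance_from_sd_corr(sd, corr) -> np.ndarray:
    """Assemble a covariance matrix from standard deviations and correlations."""
    sd = np.asarray(sd, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (sd.size, sd.size):
        raise ConfigurationError("correlation matrix shape does not match SD vector")
    if not np.allclose(corr, corr.T):
        raise ConfigurationError("correlation matrix must be symmetric")
    return corr * np.outer(sd, sd)


def check_positive_definite(mat: np.ndarray, name: str = "covariance") -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigurationError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ConfigurationError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(f"{name} is not positive definite") from exc


@dataclass
class DesignSpec:
    """Names of the expanded baseline covariates entering each linear predictor.

    Covariate names refer to columns of the *expanded* baseline table
    (categoricals dummy-coded against their reference category: female,
    urban is its own indicator with rural as reference, enalapril,
    monotherapy).  ``time`` always enters each marker's fixed and random
    parts via the (1, t) design; it is not listed here.
    """

    sbp_covariates: tuple[str, ...]
    dbp_covariates: tuple[str, ...]
    survival_covariates: tuple[str, ...]

    def __post_init__(self):
        self.sbp_covariates = tuple(self.sbp_covariates)
        self.dbp_covariates = tuple(self.dbp_covariates)
        self.survival_covariates = tuple(self.survival_covariates)


@dataclass
class LMMParams:
    """Bivariate linear mixed model parameters.

    ``beta_*`` are the (intercept, slope-per-month) coefficients of the
    time design (1, t); ``delta_*`` the coefficients of the time-invariant
    covariates in the matching ``DesignSpec`` order; ``Sigma`` the 4x4
    random-effect covariance over ``RANDOM_EFFECTS``; ``sigma_eps`` the
    residual SDs (SBP, DBP) in mmHg.
    """

    beta_sbp: np.ndarray
    beta_dbp: np.ndarray
    delta_sbp: np.ndarray
    delta_dbp: np.ndarray
    Sigma: np.ndarray
    sigma_eps: np.ndarray

    def __post_init__(self):
        self.beta_sbp = np.asarray(self.beta_sbp, dtype=float)
        self.beta_dbp = np.asarray(self.beta_dbp, dtype=float)
        self.delta_sbp = np.asarray(self.delta_sbp, dtype=float)
        self.delta_dbp = np.asarray(self.delta_dbp, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.sigma_eps = np.asarray(self.sigma_eps, dtype=float)

    def validate(self) -> None:
        if self.beta_sbp.shape != (2,) or self.beta_dbp.shape != (2,):
            raise ConfigurationError("beta vectors must be (intercept, slope)")
        if self.Sigma.shape != (4, 4):
            raise ConfigurationError("Sigma must be 4x4")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ConfigurationError("Sigma must be symmetric")
        eig = np.linalg.eigvalsh(self.Sigma)
        if eig.min() < -1e-10:
            raise ConfigurationError("Sigma must be positive semidefinite")
        if np.any(self.sigma_eps < 0):
            raise ConfigurationError("residual SDs must be non-negative")


@dataclass
class HazardParams:
    """Proportional-hazards sub-model parameters.

    The baseline hazard is piecewise constant: level ``exp(log_baseline[k])``
    applies on ``[knots[k], knots[k+1])`` and the last level extends beyond
    the final knot.  ``gamma`` are log hazard ratios for the survival
    covariates; ``rho`` is the association vector over ``ASSOCIATION_TERMS``
    (per-mmHg for the value terms, per mmHg/month for the slope terms).
    """

    log_baseline: np.ndarray
    knots: np.ndarray
    gamma: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.log_baseline = np.atleast_1d(np.asarray(self.log_baseline, dtype=float))
        self.knots = np.atleast_1d(np.asarray(self.knots, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.rho = np.asarray(self.rho, dtype=float)

    def validate(self) -> None:
        if self.knots.size != self.log_baseline.size:
            raise ConfigurationError("need one baseline level per knot interval")
        if self.knots[0] != 0 or np.any(np.diff(self.knots) <= 0):
            raise ConfigurationError("knots must be strictly increasing and start at 0")
        if not np.all(np.isfinite(self.log_baseline)):
            raise ConfigurationError("baseline log-hazard levels must be finite")
        if self.rho.shape != (4,):
            raise ConfigurationError("rho must have 4 elements (value/slope x SBP/DBP)")


@dataclass
class ShrinkageHyper:
    """Global-local ridge shrinkage scales for the association vector.

    Each association coefficient has prior N(0, tau * psi_s): the global
    scale ``tau`` shrinks all coefficients while the local scales ``psi``
    let individual ones escape.
    """

    tau: float = 1.0
    psi: np.ndarray = field(default_factory=lambda: np.ones(4))

    def __post_init__(self):
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))

    def validate(self) -> None:
        if self.tau <= 0 or np.any(self.psi <= 0):
            raise ConfigurationError("shrinkage scales must be strictly positive")


@dataclass
class JointParams:
    """All parameters of the joint model; also serves as simulation truth."""

    lmm: LMMParams
    hazard: HazardParams
    shrinkage: ShrinkageHyper = field(default_factory=ShrinkageHyper)

    def validate(self) -> None:
        self.lmm.validate()
        self.hazard.validate()
        self.shrinkage.validate()

    def copy(self) -> "JointParams":
        return JointParams(
            lmm=LMMParams(
                self.lmm.beta_sbp.copy(),
                self.lmm.beta_dbp.copy(),
                self.lmm.delta_sbp.copy(),
                self.lmm.delta_dbp.copy(),
                self.lmm.Sigma.copy(),
                self.lmm.sigma_eps.copy(),
            ),
            hazard=HazardParams(
                self.hazard.log_baseline.copy(),
                self.hazard.knots.copy(),
                self.hazard.gamma.copy(),
                self.hazard.rho.copy(),
            ),
            shrinkage=ShrinkageHyper(self.shrinkage.tau, self.shrinkage.psi.copy()),
        )


#: alias used by the synthetic cohort generator
TruthParams = JointParams
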