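import numpy as np
import pytest

import bpjoint as bj


@pytest.fixture(scope="session")
def truth():
    """Default generating parameters (study-estimate defaults)."""
    return bj.default_truth()


@pytest.fixture(scope="session")
def design():
    return bj.default_design()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject cohort with quarterly visits; shared across tests."""
    cfg = bj.CohortConfig(n_subjects=40, visit_schedule=tuple(float(t) for t in range(0, 30, 3)), seed=3)
    cohort, lng, surv, truth = bj.generate_cohort(cfg)
    return cfg, cohort, lng, surv, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def zero_lmm(n_sbp: int = 0, n_dbp: int | None = None):
    """LMM parameters that make every trajectory identically zero."""
    return bj.LMMParams(
        beta_sbp=np.zeros(2),
        beta_dbp=np.zeros(2),
        delta_sbp=np.zeros(n_sbp),
        delta_dbp=np.zeros(n_sbp if n_dbp is None else n_dbp),
        Sigma=np.zeros((4, 4)),
        sigma_eps=np.zeros(2),
    )


def constant_hazard(level: float, gamma=(), rho=(0.0, 0.0, 0.0, 0.0)):
    """Single-interval (constant) baseline hazard."""
    return bj.HazardParams(
        log_baseline=np.array([np.log(level)]),
        knots=np.array([0.0]),
        gamma=np.asarray(gamma, dtype=float),
        rho=np.asarray(rho, dtype=float),
    )
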