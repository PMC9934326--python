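"""Bayesian inference for the joint model.

Posterior:  f(theta, b | Y, T) proportional to

    [prod_ij N(y_ij; m_i(t_ij), sigma_eps^2)]          (longitudinal)
  * [prod_i h_i(T_i)^d_i exp(-Lambda_i(T_i))]          (survival)
  * [prod_i N(b_i; 0, Sigma)]                          (random effects)
  * pi(theta)                                          (priors)

Priors: N(0, 1000) on every longitudinal fixed effect, survival
coefficient and baseline log-hazard level; a global-local ridge
shrinkage prior on the association vector, rho_s ~ N(0, tau * psi_s)
with tau^-1 ~ Gamma(0.1, 0.1) and psi_s^-1 ~ Gamma(1, 0.01);
Sigma ~ inverse-Wishart(5, I); sigma_eps^2 ~ inverse-Gamma(0.01, 0.01).

The sampler is Metropolis-within-Gibbs:

* longitudinal fixed effects: drawn from their Gaussian full conditional
  given the random effects (exact when rho = 0); because they also enter
  the hazard through m_i(t), the draw is used as an independence proposal
  and corrected by the survival likelihood ratio — exact in general;
* an interweaving re-centering step for the four (intercept, slope)
  coefficients, which removes the slow mixing of centred intercepts
  against the random-effect means (the survival likelihood is invariant
  under the move, so the step is plain conjugate);
* per-subject random effects: adaptive random-walk Metropolis,
  preconditioned by the current Sigma, targeting 0.234 acceptance;
* residual variances and Sigma: conjugate inverse-Gamma / inverse-Wishart;
* baseline log-hazards, survival coefficients and association vector:
  one adaptive random-walk block with the empirical proposal covariance
  learned during burn-in (internally the block is sampled on a centred
  scale in which the marker values are measured as deviations from their
  sample means, which decorrelates the association from the baseline
  levels; reported draws are on the original scale);
* shrinkage hyper-parameters: exact Gamma full conditionals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults
from .design import covariate_matrix
from .errors import ConfigurationError, SchemaError
from .longitudinal import loglik_longitudinal
from .params import (
    ASSOCIATION_TERMS,
    RANDOM_EFFECTS,
    DesignSpec,
    HazardParams,
    JointParams,
    LMMParams,
    ShrinkageHyper,
)
from .survival import (
    GAUSS_LEGENDRE_ORDER,
    baseline_level_index,
    loglik_event,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# conjugate full conditionals (shared by the sampler and its unit tests)
# --------------------------------------------------------------------------


def beta_full_conditional(F, FtF, ytil, s2):
    """Gaussian full conditional of a marker's fixed effects.

    Given random effects (already subtracted from ``ytil``) and residual
    variance ``s2``, the conditional is N(mean, prec^-1) with
    prec = F'F / s2 + I / 1000.  Returns (mean, cholesky(prec)).
    """
    prec = FtF / s2 + np.eye(F.shape[1]) / PRIOR_COEF_VAR
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, F.T @ ytil / s2)
    return mean, chol


def draw_sigma_eps2(ssr, n_obs, rng):
    """Conjugate inverse-Gamma draw of one residual variance."""
    return 1.0 / rng.gamma(
        SIGMA_EPS_PRIOR[0] + n_obs / 2.0, 1.0 / (SIGMA_EPS_PRIOR[1] + ssr / 2.0)
    )


def draw_sigma(b, rng):
    """Conjugate inverse-Wishart draw of the random-effect covariance."""
    scale = np.eye(4) + b.T @ b
    W = stats.wishart.rvs(
        df=SIGMA_PRIOR_DF + b.shape[0], scale=np.linalg.inv(scale), random_state=rng
    )
    Sigma = np.linalg.inv(W)
    return 0.5 * (Sigma + Sigma.T)


# --------------------------------------------------------------------------
# priors and shrinkage
# --------------------------------------------------------------------------

PRIOR_COEF_VAR = 1000.0
SIGMA_PRIOR_DF = 5.0
SIGMA_EPS_PRIOR = (0.01, 0.01)     # inverse-Gamma shape, scale
TAU_PRIOR = (0.1, 0.1)             # Gamma shape, rate on tau^-1
PSI_PRIOR = (1.0, 0.01)            # Gamma shape, rate on psi_s^-1


def _normal_logpdf(x, var):
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * (_LOG_2PI + np.log(var) + x**2 / var)))


def log_prior(params: JointParams) -> float:
    """Log prior density of a full parameter point.

    Sums N(0, 1000) terms for the longitudinal fixed effects, the survival
    coefficients and the baseline log-hazard levels; N(0, tau*psi_s) for
    each association coefficient; the Gamma(0.1, 0.1) / Gamma(1, 0.01)
    hyper-priors on the inverse shrinkage scales; inverse-Wishart(5, I)
    for Sigma and inverse-Gamma(0.01, 0.01) for each residual variance.
    """
    params.validate()
    lmm, hz, sh = params.lmm, params.hazard, params.shrinkage
    lp = _normal_logpdf(
        np.concatenate([lmm.beta_sbp, lmm.beta_dbp, lmm.delta_sbp, lmm.delta_dbp]),
        PRIOR_COEF_VAR,
    )
    lp += _normal_logpdf(hz.gamma, PRIOR_COEF_VAR)
    lp += _normal_logpdf(hz.log_baseline, PRIOR_COEF_VAR)
    lp += float(np.sum(stats.norm.logpdf(hz.rho, scale=np.sqrt(sh.tau * sh.psi))))
    lp += float(stats.invgamma.logpdf(sh.tau, TAU_PRIOR[0], scale=TAU_PRIOR[1]))
    lp += float(np.sum(stats.invgamma.logpdf(sh.psi, PSI_PRIOR[0], scale=PSI_PRIOR[1])))
    lp += float(
        stats.invwishart.logpdf(lmm.Sigma, SIGMA_PRIOR_DF, np.eye(4))
    )
    lp += float(
        np.sum(
            stats.invgamma.logpdf(
                lmm.sigma_eps**2, SIGMA_EPS_PRIOR[0], scale=SIGMA_EPS_PRIOR[1]
            )
        )
    )
    return lp


def sample_shrinkage(
    rho: np.ndarray, hyper: ShrinkageHyper, rng: np.random.Generator
) -> ShrinkageHyper:
    """Exact Gamma full-conditional draws of the shrinkage hyper-parameters.

    tau^-1 | rho, psi ~ Gamma(0.1 + S/2, 0.1 + sum_s rho_s^2 / (2 psi_s))
    psi_s^-1 | rho, tau ~ Gamma(1 + 1/2, 0.01 + rho_s^2 / (2 tau))
    """
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ConfigurationError("association vector must be finite")
    s = rho.size
    rate_tau = TAU_PRIOR[1] + float(np.sum(rho**2 / (2.0 * hyper.psi)))
    tau_inv = rng.gamma(TAU_PRIOR[0] + s / 2.0, 1.0 / rate_tau)
    tau = 1.0 / tau_inv
    rate_psi = PSI_PRIOR[1] + rho**2 / (2.0 * tau)
    psi = 1.0 / rng.gamma(PSI_PRIOR[0] + 0.5, 1.0 / rate_psi)
    return ShrinkageHyper(tau=tau, psi=psi)


def log_posterior(
    params: JointParams,
    effects: np.ndarray,
    cohort: pd.DataFrame,
    long_table: pd.DataFrame,
    survival: pd.DataFrame,
    spec: DesignSpec | None = None,
) -> float:
    """Unnormalised log posterior density at one (theta, b) point."""
    spec = spec or defaults.default_design()
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    ll = loglik_longitudinal(params.lmm, effects, long_table, cohort, spec)
    u1 = covariate_matrix(cohort, spec.sbp_covariates)
    u2 = covariate_matrix(cohort, spec.dbp_covariates)
    us = covariate_matrix(cohort, spec.survival_covariates)
    from .survival import trajectory_coefficients

    traj = trajectory_coefficients(params.lmm, effects, u1, u2)
    surv = survival.set_index("id")
    for k, sid in enumerate(cohort["id"]):
        row = surv.loc[sid]
        ll += loglik_event(
            float(row["time_months"]), int(row["event"]), traj[k], us[k], params.hazard
        )
    ll += float(
        np.sum(
            stats.multivariate_normal.logpdf(
                effects, mean=np.zeros(4), cov=params.lmm.Sigma, allow_singular=True
            )
        )
    )
    return ll + log_prior(params)


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------


@dataclass
class ModelData:
    """Pre-assembled arrays for the sampler (internal)."""

    ids: np.ndarray
    n: int
    U1: np.ndarray
    U2: np.ndarray
    US: np.ndarray
    idx: np.ndarray       # longitudinal row -> subject index
    t: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    F1: np.ndarray        # [1, t, U1[idx]]
    F2: np.ndarray
    T: np.ndarray         # survival times
    delta: np.ndarray     # event indicators
    knots: np.ndarray
    T_lev: np.ndarray
    node_t: np.ndarray
    node_w: np.ndarray
    node_subj: np.ndarray
    node_lev: np.ndarray
    n_i: np.ndarray       # visits per subject
    St: np.ndarray
    Stt: np.ndarray
    US_mean: np.ndarray
    m_ref: np.ndarray     # centring constants (mean SBP, 0, mean DBP, 0)
    spec: DesignSpec


def choose_knots(event_times: np.ndarray, n_intervals: int) -> np.ndarray:
    """Piecewise-constant baseline knots at event-time quantiles."""
    if event_times.size == 0:
        raise ConfigurationError(
            "no events observed: baseline hazard is not identifiable"
        )
    probs = np.arange(1, n_intervals) / n_intervals
    inner = np.unique(np.quantile(event_times, probs))
    inner = inner[inner > 0]
    return np.concatenate([[0.0], inner])


def prepare_model_data(
    cohort: pd.DataFrame,
    long_table: pd.DataFrame,
    survival: pd.DataFrame,
    spec: DesignSpec,
    n_intervals: int = 5,
    knots: np.ndarray | None = None,
) -> ModelData:
    ids = cohort["id"].to_numpy()
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate subject ids in baseline table")
    surv = survival.set_index("id")
    if set(surv.index) != set(ids) or set(long_table["id"]) - set(ids):
        raise SchemaError("subject ids are inconsistent across tables")
    pos = {i: k for k, i in enumerate(ids)}
    idx = np.array([pos[i] for i in long_table["id"]], dtype=int)
    t = long_table["time_months"].to_numpy(dtype=float)
    y1 = long_table["sbp_mmhg"].to_numpy(dtype=float)
    y2 = long_table["dbp_mmhg"].to_numpy(dtype=float)
    U1 = covariate_matrix(cohort, spec.sbp_covariates)
    U2 = covariate_matrix(cohort, spec.dbp_covariates)
    US = covariate_matrix(cohort, spec.survival_covariates)
    F1 = np.column_stack([np.ones_like(t), t, U1[idx]])
    F2 = np.column_stack([np.ones_like(t), t, U2[idx]])
    T = surv.loc[ids, "time_months"].to_numpy(dtype=float)
    delta = surv.loc[ids, "event"].to_numpy(dtype=int)
    if delta.sum() == 0:
        raise ConfigurationError(
            "no events observed: baseline hazard is not identifiable"
        )
    if knots is None:
        knots = choose_knots(T[delta == 1], n_intervals)
    knots = np.asarray(knots, dtype=float)
    n = len(ids)
    nodes, weights = np.polynomial.legendre.leggauss(GAUSS_LEGENDRE_ORDER)
    node_t, node_w, node_subj = [], [], []
    for i in range(n):
        edges = np.concatenate([knots[knots < T[i]], [T[i]]])
        for a, b in zip(edges[:-1], edges[1:]):
            half = 0.5 * (b - a)
            node_t.append(a + half * (nodes + 1.0))
            node_w.append(half * weights)
            node_subj.append(np.full(nodes.size, i))
    node_t = np.concatenate(node_t)
    node_w = np.concatenate(node_w)
    node_subj = np.concatenate(node_subj)
    return ModelData(
        ids=ids,
        n=n,
        U1=U1,
        U2=U2,
        US=US,
        idx=idx,
        t=t,
        y1=y1,
        y2=y2,
        F1=F1,
        F2=F2,
        T=T,
        delta=delta,
        knots=knots,
        T_lev=baseline_level_index(T, knots),
        node_t=node_t,
        node_w=node_w,
        node_subj=node_subj,
        node_lev=baseline_level_index(node_t, knots),
        n_i=np.bincount(idx, minlength=n).astype(float),
        St=np.bincount(idx, weights=t, minlength=n),
        Stt=np.bincount(idx, weights=t**2, minlength=n),
        US_mean=US.mean(axis=0) if len(US) else np.zeros(US.shape[1]),
        m_ref=np.array([float(np.mean(y1)), 0.0, float(np.mean(y2)), 0.0]),
        spec=spec,
    )


# --------------------------------------------------------------------------
# sampler configuration and output container
# --------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Sampler settings; the defaults are the production run."""

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    n_intervals: int = 5
    #: "value_slope" (default), "value", or "slope"
    association: str = "value_slope"
    #: fix the association vector instead of sampling it (e.g. zeros)
    fix_rho: np.ndarray | None = None
    #: Metropolis refreshes of the survival block per Gibbs sweep; the
    #: block is cheap relative to the rest of the sweep and its
    #: parameters (baseline levels, gamma, rho) mix slowest
    survival_updates: int = 5
    target_accept: float = 0.234
    rhat_threshold: float = 1.1

    def validate(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ConfigurationError("n_iter must exceed burn_in")
        if self.thin < 1 or self.n_chains < 1:
            raise ConfigurationError("thin and n_chains must be >= 1")
        if self.association not in ("value_slope", "value", "slope"):
            raise ConfigurationError("association must be value_slope, value or slope")


def _association_mask(kind: str) -> np.ndarray:
    return {
        "value_slope": np.array([True, True, True, True]),
        "value": np.array([True, False, True, False]),
        "slope": np.array([False, True, False, True]),
    }[kind]


@dataclass
class PosteriorChains:
    """MCMC draws with convergence diagnostics and posterior summaries.

    ``draws`` maps parameter-group names to arrays of shape
    (chains, draws) or (chains, draws, dim).  ``summary()`` flattens to a
    per-parameter table with posterior mean, SD, Monte-Carlo SE, central
    95% credible interval, R-hat and effective sample size.
    """

    draws: dict
    param_names: dict
    pointwise_loglik: np.ndarray   # (chains, draws, subjects)
    total_loglik: np.ndarray       # (chains, draws)
    b_mean: np.ndarray             # posterior mean random effects (n, 4)
    acceptance: dict
    knots: np.ndarray
    config: MCMCConfig
    spec: DesignSpec
    model_data: ModelData = field(repr=False, default=None)

    def flat(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one flat parameter, pooled over chains."""
        for group, labels in self.param_names.items():
            if name in labels:
                j = labels.index(name)
                arr = self.draws[group]
                return arr[..., j].reshape(-1) if arr.ndim == 3 else arr.reshape(-1)
        raise KeyError(name)

    def _flat_iter(self):
        for group, labels in self.param_names.items():
            arr = self.draws[group]
            for j, label in enumerate(labels):
                yield label, (arr[..., j] if arr.ndim == 3 else arr)

    def summary(self) -> pd.DataFrame:
        import arviz as az

        rows = []
        for label, chains in self._flat_iter():
            flatd = chains.reshape(-1)
            rhat = float(az.rhat(chains[None] if chains.ndim == 1 else chains))
            ess = float(az.ess(chains[None] if chains.ndim == 1 else chains))
            rows.append(
                {
                    "parameter": label,
                    "post_mean": float(np.mean(flatd)),
                    "post_sd": float(np.std(flatd, ddof=1)),
                    "mcse": float(np.std(flatd, ddof=1) / np.sqrt(max(ess, 1.0))),
                    "ci_2.5%": float(np.quantile(flatd, 0.025)),
                    "ci_97.5%": float(np.quantile(flatd, 0.975)),
                    "rhat": rhat,
                    "ess": ess,
                }
            )
        out = pd.DataFrame(rows).set_index("parameter")
        out.attrs["converged"] = bool(
            (out["rhat"] < self.config.rhat_threshold).all()
        )
        return out

    def posterior_mean_params(self) -> JointParams:
        """Point estimate assembled from per-parameter posterior means."""

        def m(group):
            arr = self.draws[group]
            return np.mean(arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr, axis=0)

        Sigma = np.mean(self.draws["Sigma"].reshape(-1, 4, 4), axis=0)
        lmm = LMMParams(
            beta_sbp=m("beta_sbp")[:2],
            beta_dbp=m("beta_dbp")[:2],
            delta_sbp=m("beta_sbp")[2:],
            delta_dbp=m("beta_dbp")[2:],
            Sigma=Sigma,
            sigma_eps=m("sigma_eps"),
        )
        hazard = HazardParams(
            log_baseline=m("log_h0"),
            knots=self.knots,
            gamma=m("gamma") if "gamma" in self.draws else np.empty(0),
            rho=m("rho"),
        )
        sh = ShrinkageHyper(
            tau=float(np.mean(self.draws["tau"])), psi=m("psi")
        )
        return JointParams(lmm=lmm, hazard=hazard, shrinkage=sh)


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


def _surv_loglik(md, A1, B1, A2, B2, logh0c, gamma, rho):
    """Per-subject survival log-likelihood on the centred scale.

    ``logh0c`` are the centred baseline levels; the marker values enter
    as deviations from md.m_ref and the survival covariates as deviations
    from their means.
    """
    usc = (md.US - md.US_mean) @ gamma
    g = usc + rho[1] * (B1 - md.m_ref[1]) + rho[3] * (B2 - md.m_ref[3])
    m1T = A1 + B1 * md.T - md.m_ref[0]
    m2T = A2 + B2 * md.T - md.m_ref[2]
    loghT = logh0c[md.T_lev] + g + rho[0] * m1T + rho[2] * m2T
    s = md.node_subj
    m1q = A1[s] + B1[s] * md.node_t - md.m_ref[0]
    m2q = A2[s] + B2[s] * md.node_t - md.m_ref[2]
    with np.errstate(over="ignore"):
        lam = np.bincount(
            s,
            weights=md.node_w
            * np.exp(logh0c[md.node_lev] + g[s] + rho[0] * m1q + rho[2] * m2q),
            minlength=md.n,
        )
    return md.delta * loghT - lam


def _uncentre_logh0(md, logh0c, gamma, rho):
    """Baseline levels on the original (uncentred) scale."""
    shift = float(md.US_mean @ gamma + rho @ md.m_ref)
    return logh0c - shift


def _run_chain(md: ModelData, cfg: MCMCConfig, seed):
    rng = np.random.default_rng(seed)
    n, K = md.n, md.knots.size
    q = md.US.shape[1]
    p1, p2 = md.F1.shape[1], md.F2.shape[1]

    mask = _association_mask(cfg.association)
    fix_rho = cfg.fix_rho is not None
    rho = np.zeros(4) if not fix_rho else np.asarray(cfg.fix_rho, dtype=float).copy()

    # --- initial values: per-marker least squares, exponential hazard fit
    bet1, *_ = np.linalg.lstsq(md.F1, md.y1, rcond=None)
    bet2, *_ = np.linalg.lstsq(md.F2, md.y2, rcond=None)
    # subject-level least-squares residual fits seed b and Sigma at a
    # realistic scale (a zero start would collapse the conjugate Sigma
    # update before the random effects can grow)
    b = np.zeros((n, 4))
    for marker, (bet, y, c0) in enumerate(
        ((bet1, md.y1, 0), (bet2, md.y2, 2))
    ):
        r0 = y - (md.F1 if marker == 0 else md.F2) @ bet
        Sr = np.bincount(md.idx, weights=r0, minlength=n)
        Srt = np.bincount(md.idx, weights=r0 * md.t, minlength=n)
        det = md.n_i * md.Stt - md.St**2
        multi = det > 1e-8
        b[multi, c0] = (md.Stt[multi] * Sr[multi] - md.St[multi] * Srt[multi]) / det[multi]
        b[multi, c0 + 1] = (md.n_i[multi] * Srt[multi] - md.St[multi] * Sr[multi]) / det[multi]
        b[~multi, c0] = Sr[~multi] / np.maximum(md.n_i[~multi], 1.0)
    sig2 = np.array(
        [
            np.var(md.y1 - md.F1 @ bet1 - b[md.idx, 0] - b[md.idx, 1] * md.t),
            np.var(md.y2 - md.F2 @ bet2 - b[md.idx, 2] - b[md.idx, 3] * md.t),
        ]
    )
    sig2 = np.maximum(sig2, 1.0)
    Sigma = np.cov(b.T) + np.diag([1.0, 0.01, 1.0, 0.01])
    exposure = np.bincount(
        md.node_lev, weights=md.node_w, minlength=K
    )
    ev_per = np.bincount(md.T_lev[md.delta == 1], minlength=K)
    logh0c = np.log((ev_per + 0.5) / np.maximum(exposure, 1e-12))
    gamma = np.zeros(q)
    hyper = ShrinkageHyper()

    FtF1 = md.F1.T @ md.F1
    FtF2 = md.F2.T @ md.F2
    base_c1 = md.U1 @ bet1[2:]
    base_c2 = md.U2 @ bet2[2:]

    def AB():
        return (
            bet1[0] + base_c1 + b[:, 0],
            bet1[1] + b[:, 1],
            bet2[0] + base_c2 + b[:, 2],
            bet2[1] + b[:, 3],
        )

    sl = _surv_loglik(md, *AB(), logh0c, gamma, rho)

    # adaptation state
    log_step_b = np.full(n, np.log(0.5))
    phi_dim = K + q + int(mask.sum()) * (0 if fix_rho else 1)
    phi_scales = np.concatenate(
        [np.full(K, 0.15), np.full(q, 0.10), ([] if fix_rho else np.full(int(mask.sum()), 0.01))]
    )
    phi_cov = np.diag(phi_scales**2)
    phi_hist_mean = np.zeros(phi_dim)
    phi_hist_m2 = np.zeros((phi_dim, phi_dim))
    phi_count = 0
    log_phi_scale = 0.0
    acc_b = acc_phi = acc_beta = 0.0
    n_phi = n_beta = 0

    n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
    out = {
        "beta_sbp": np.empty((n_keep, p1)),
        "beta_dbp": np.empty((n_keep, p2)),
        "sigma_eps": np.empty((n_keep, 2)),
        "Sigma": np.empty((n_keep, 4, 4)),
        "log_h0": np.empty((n_keep, K)),
        "gamma": np.empty((n_keep, q)),
        "rho": np.empty((n_keep, 4)),
        "tau": np.empty(n_keep),
        "psi": np.empty((n_keep, 4)),
    }
    pw = np.empty((n_keep, n))
    total = np.empty(n_keep)
    b_sum = np.zeros((n, 4))
    keep = 0

    for it in range(cfg.n_iter):
        adapting = it < cfg.burn_in
        gain = 1.0 / (1.0 + it) ** 0.6

        # ---- (1) fixed effects, per marker: conjugate proposal + survival MH
        for marker in (1, 2):
            F = md.F1 if marker == 1 else md.F2
            FtF = FtF1 if marker == 1 else FtF2
            y = md.y1 if marker == 1 else md.y2
            cols = (0, 1) if marker == 1 else (2, 3)
            rand = b[md.idx, cols[0]] + b[md.idx, cols[1]] * md.t
            ytil = y - rand
            s2 = sig2[marker - 1]
            mean, chol = beta_full_conditional(F, FtF, ytil, s2)
            prop = mean + np.linalg.solve(chol.T, rng.standard_normal(F.shape[1]))
            cur = bet1 if marker == 1 else bet2
            if (marker == 1 and (rho[0] != 0 or rho[1] != 0)) or (
                marker == 2 and (rho[2] != 0 or rho[3] != 0)
            ):
                c_prop = (md.U1 if marker == 1 else md.U2) @ prop[2:]
                if marker == 1:
                    A1p, B1p = prop[0] + c_prop + b[:, 0], prop[1] + b[:, 1]
                    sl_prop = _surv_loglik(
                        md, A1p, B1p, *AB()[2:], logh0c, gamma, rho
                    )
                else:
                    A2p, B2p = prop[0] + c_prop + b[:, 2], prop[1] + b[:, 3]
                    sl_prop = _surv_loglik(
                        md, *AB()[:2], A2p, B2p, logh0c, gamma, rho
                    )
                lr = float(np.sum(sl_prop - sl))
                accept = np.log(rng.uniform()) < lr
            else:
                accept = True
            if accept:
                if marker == 1:
                    bet1 = prop
                    base_c1 = md.U1 @ bet1[2:]
                else:
                    bet2 = prop
                    base_c2 = md.U2 @ bet2[2:]
                sl = _surv_loglik(md, *AB(), logh0c, gamma, rho)
            acc_beta += float(accept)
            n_beta += 1

        # ---- (2) interweaving re-centring of (intercept, slope) pairs
        theta = np.array([bet1[0], bet1[1], bet2[0], bet2[1]])
        btil = b + theta
        Sinv = np.linalg.inv(Sigma)
        prec_t = n * Sinv + np.eye(4) / PRIOR_COEF_VAR
        mean_t = np.linalg.solve(prec_t, Sinv @ btil.sum(axis=0))
        chol_t = np.linalg.cholesky(prec_t)
        theta_new = mean_t + np.linalg.solve(chol_t.T, rng.standard_normal(4))
        b = btil - theta_new
        bet1[0], bet1[1] = theta_new[0], theta_new[1]
        bet2[0], bet2[1] = theta_new[2], theta_new[3]
        # trajectories (and hence sl) are invariant under this move

        # ---- (3) random effects: preconditioned random-walk Metropolis
        r01 = md.y1 - md.F1 @ bet1
        r02 = md.y2 - md.F2 @ bet2
        Sr1 = np.bincount(md.idx, weights=r01, minlength=n)
        Srt1 = np.bincount(md.idx, weights=r01 * md.t, minlength=n)
        Sr2 = np.bincount(md.idx, weights=r02, minlength=n)
        Srt2 = np.bincount(md.idx, weights=r02 * md.t, minlength=n)

        def long_quad(bb):
            q1 = (
                -2 * bb[:, 0] * Sr1
                - 2 * bb[:, 1] * Srt1
                + bb[:, 0] ** 2 * md.n_i
                + 2 * bb[:, 0] * bb[:, 1] * md.St
                + bb[:, 1] ** 2 * md.Stt
            )
            q2 = (
                -2 * bb[:, 2] * Sr2
                - 2 * bb[:, 3] * Srt2
                + bb[:, 2] ** 2 * md.n_i
                + 2 * bb[:, 2] * bb[:, 3] * md.St
                + bb[:, 3] ** 2 * md.Stt
            )
            return -0.5 * (q1 / sig2[0] + q2 / sig2[1])

        cholS = np.linalg.cholesky(Sigma)
        bp = b + np.exp(log_step_b)[:, None] * (rng.standard_normal((n, 4)) @ cholS.T)
        A1, B1, A2, B2 = AB()
        A1p = A1 + (bp[:, 0] - b[:, 0])
        B1p = B1 + (bp[:, 1] - b[:, 1])
        A2p = A2 + (bp[:, 2] - b[:, 2])
        B2p = B2 + (bp[:, 3] - b[:, 3])
        sl_prop = _surv_loglik(md, A1p, B1p, A2p, B2p, logh0c, gamma, rho)
        prior_cur = -0.5 * np.einsum("ij,ij->i", b @ Sinv, b)
        prior_prop = -0.5 * np.einsum("ij,ij->i", bp @ Sinv, bp)
        diff = (
            long_quad(bp)
            - long_quad(b)
            + sl_prop
            - sl
            + prior_prop
            - prior_cur
        )
        acc = np.log(rng.uniform(size=n)) < diff
        b[acc] = bp[acc]
        sl[acc] = sl_prop[acc]
        A1 = np.where(acc, A1p, A1)
        B1 = np.where(acc, B1p, B1)
        A2 = np.where(acc, A2p, A2)
        B2 = np.where(acc, B2p, B2)
        if adapting:
            with np.errstate(over="ignore"):
                ap = np.minimum(1.0, np.exp(diff))
            log_step_b += gain * (ap - cfg.target_accept)
        acc_b += float(np.mean(acc))

        # ---- (4) residual variances: conjugate inverse-Gamma
        rand1 = b[md.idx, 0] + b[md.idx, 1] * md.t
        rand2 = b[md.idx, 2] + b[md.idx, 3] * md.t
        ssr1 = float(np.sum((r01 - rand1) ** 2))
        ssr2 = float(np.sum((r02 - rand2) ** 2))
        N = md.t.size
        sig2[0] = draw_sigma_eps2(ssr1, N, rng)
        sig2[1] = draw_sigma_eps2(ssr2, N, rng)

        # ---- (5) random-effect covariance: conjugate inverse-Wishart
        Sigma = draw_sigma(b, rng)

        # ---- (6) survival block: adaptive Metropolis on (log h0, gamma, rho)
        free_rho = 0 if fix_rho else int(mask.sum())
        for _ in range(max(1, cfg.survival_updates)):
            phi = np.concatenate(
                [logh0c, gamma, rho[mask] if free_rho else []]
            )
            Lp = np.linalg.cholesky(
                phi_cov * np.exp(2 * log_phi_scale) + 1e-12 * np.eye(phi_dim)
            )
            phi_prop = phi + Lp @ rng.standard_normal(phi_dim)
            logh0c_p = phi_prop[:K]
            gamma_p = phi_prop[K : K + q]
            rho_p = rho.copy()
            if free_rho:
                rho_p[mask] = phi_prop[K + q :]
            sl_prop = _surv_loglik(md, A1, B1, A2, B2, logh0c_p, gamma_p, rho_p)
            # priors live on the uncentred baseline scale
            lp_cur = _normal_logpdf(
                _uncentre_logh0(md, logh0c, gamma, rho), PRIOR_COEF_VAR
            ) + _normal_logpdf(gamma, PRIOR_COEF_VAR)
            lp_prop = _normal_logpdf(
                _uncentre_logh0(md, logh0c_p, gamma_p, rho_p), PRIOR_COEF_VAR
            ) + _normal_logpdf(gamma_p, PRIOR_COEF_VAR)
            if not fix_rho:
                var_rho = hyper.tau * hyper.psi
                lp_cur += float(np.sum(-0.5 * rho[mask] ** 2 / var_rho[mask]))
                lp_prop += float(np.sum(-0.5 * rho_p[mask] ** 2 / var_rho[mask]))
            lr = float(np.sum(sl_prop - sl)) + lp_prop - lp_cur
            if np.log(rng.uniform()) < lr:
                logh0c, gamma, rho = logh0c_p, gamma_p, rho_p
                sl = sl_prop
                acc_phi += 1.0
            n_phi += 1
            if adapting:
                phi_count += 1
                d = phi - phi_hist_mean
                phi_hist_mean += d / phi_count
                phi_hist_m2 += np.outer(d, phi - phi_hist_mean)
                if phi_count > 100:
                    emp = phi_hist_m2 / (phi_count - 1)
                    phi_cov = (2.38**2 / phi_dim) * (emp + 1e-10 * np.eye(phi_dim))
                ap = min(1.0, np.exp(min(lr, 0.0)))
                log_phi_scale += gain * (ap - cfg.target_accept)

        # ---- (7) shrinkage hyper-parameters: exact full conditionals
        if not fix_rho:
            hyper = sample_shrinkage(rho, hyper, rng)

        # ---- store
        if not adapting and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            out["beta_sbp"][keep] = bet1
            out["beta_dbp"][keep] = bet2
            out["sigma_eps"][keep] = np.sqrt(sig2)
            out["Sigma"][keep] = Sigma
            out["log_h0"][keep] = _uncentre_logh0(md, logh0c, gamma, rho)
            out["gamma"][keep] = gamma
            out["rho"][keep] = rho
            out["tau"][keep] = hyper.tau
            out["psi"][keep] = hyper.psi
            # pointwise conditional log-likelihood per subject
            res1 = r01 - rand1
            res2 = r02 - rand2
            ll1 = np.bincount(md.idx, weights=res1**2, minlength=n) / sig2[0]
            ll2 = np.bincount(md.idx, weights=res2**2, minlength=n) / sig2[1]
            long_pw = -0.5 * (
                md.n_i * (2 * _LOG_2PI + np.log(sig2[0]) + np.log(sig2[1])) + ll1 + ll2
            )
            pw[keep] = long_pw + sl
            total[keep] = float(np.sum(pw[keep]))
            b_sum += b
            keep += 1

    acceptance = {
        "random_effects": acc_b / cfg.n_iter,
        "survival_block": acc_phi / max(n_phi, 1),
        "fixed_effects": acc_beta / max(n_beta, 1),
    }
    return out, pw, total, b_sum / max(keep, 1), acceptance


def run_mcmc(
    cohort: pd.DataFrame,
    long_table: pd.DataFrame,
    survival: pd.DataFrame,
    config: MCMCConfig | None = None,
    spec: DesignSpec | None = None,
) -> PosteriorChains:
    """Fit the joint model by Metropolis-within-Gibbs MCMC.

    Runs ``config.n_chains`` independent chains (seeded from the single
    master seed), discards ``burn_in`` iterations, thins, and returns a
    ``PosteriorChains`` with draws, per-subject pointwise log-likelihoods
    and acceptance rates.  Convergence should be checked via
    ``summary()``'s R-hat column (flagged against 1.1).
    """
    config = config or MCMCConfig()
    config.validate()
    spec = spec or defaults.default_design()
    md = prepare_model_data(cohort, long_table, survival, spec, config.n_intervals)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chain_out = [_run_chain(md, config, s) for s in seeds]
    draws = {
        k: np.stack([c[0][k] for c in chain_out]) for k in chain_out[0][0]
    }
    pw = np.stack([c[1] for c in chain_out])
    total = np.stack([c[2] for c in chain_out])
    b_mean = np.mean([c[3] for c in chain_out], axis=0)
    acceptance = {
        k: float(np.mean([c[4][k] for c in chain_out])) for k in chain_out[0][4]
    }
    p1 = ["sbp:intercept", "sbp:time"] + [f"sbp:{c}" for c in spec.sbp_covariates]
    p2 = ["dbp:intercept", "dbp:time"] + [f"dbp:{c}" for c in spec.dbp_covariates]
    sig_pairs = [(i, j) for i in range(4) for j in range(i, 4)]
    names = {
        "beta_sbp": p1,
        "beta_dbp": p2,
        "sigma_eps": ["sigma_eps:sbp", "sigma_eps:dbp"],
        "log_h0": [f"log_h0[{k}]" for k in range(md.knots.size)],
        "gamma": [f"gamma:{c}" for c in spec.survival_covariates],
        "rho": [f"rho:{t}" for t in ASSOCIATION_TERMS],
        "tau": ["tau"],
        "psi": [f"psi:{t}" for t in ASSOCIATION_TERMS],
    }
    # flatten Sigma into SD / correlation entries for the summary
    C, D = draws["Sigma"].shape[:2]
    sd_corr = np.empty((C, D, len(sig_pairs)))
    labels = []
    for k, (i, j) in enumerate(sig_pairs):
        S = draws["Sigma"]
        if i == j:
            sd_corr[..., k] = np.sqrt(S[..., i, i])
            labels.append(f"sd({RANDOM_EFFECTS[i]})")
        else:
            sd_corr[..., k] = S[..., i, j] / np.sqrt(S[..., i, i] * S[..., j, j])
            labels.append(f"corr({RANDOM_EFFECTS[i]},{RANDOM_EFFECTS[j]})")
    draws["sd_corr"] = sd_corr
    names["sd_corr"] = labels
    return PosteriorChains(
        draws=draws,
        param_names=names,
        pointwise_loglik=pw,
        total_loglik=total,
        b_mean=b_mean,
        acceptance=acceptance,
        knots=md.knots,
        config=config,
        spec=spec,
        model_data=md,
    )


# --------------------------------------------------------------------------
# post-processing
# --------------------------------------------------------------------------


def hazard_ratio_summary(coefficient) -> dict:
    """Hazard-ratio transform of a log-hazard coefficient (draws or point).

    Returns exp(coefficient), a central 95% interval when draws are
    given, and the percent change in the remission rate per one-unit
    increase, with its direction.
    """
    x = np.atleast_1d(np.asarray(coefficient, dtype=float))
    hr = float(np.exp(np.mean(x)))
    out = {"hr": hr}
    if x.size > 1:
        lo, hi = np.exp(np.quantile(x, [0.025, 0.975]))
        out["hr_2.5%"] = float(lo)
        out["hr_97.5%"] = float(hi)
    if hr < 1:
        out["percent_change"] = 100.0 * (1.0 - hr)
        out["direction"] = "decrease"
    elif hr > 1:
        out["percent_change"] = 100.0 * (hr - 1.0)
        out["direction"] = "increase"
    else:
        out["percent_change"] = 0.0
        out["direction"] = "none"
    return out


def model_fit_criteria(chains: PosteriorChains) -> dict:
    """DIC and WAIC from the stored pointwise log-likelihood draws.

    DIC uses the conditional deviance at the posterior means of the
    parameters and random effects, with p_D = mean deviance minus
    deviance-at-mean; WAIC uses the standard pointwise formula
    (lppd minus the pointwise posterior variances).
    """
    if chains.pointwise_loglik is None or chains.model_data is None:
        raise ConfigurationError("chains carry no stored log-likelihoods")
    pw = chains.pointwise_loglik.reshape(-1, chains.pointwise_loglik.shape[-1])
    # WAIC
    m = pw.max(axis=0)
    lppd = float(np.sum(np.log(np.mean(np.exp(pw - m), axis=0)) + m))
    p_waic = float(np.sum(np.var(pw, axis=0, ddof=1))) if pw.shape[0] > 1 else 0.0
    waic = -2.0 * (lppd - p_waic)
    # DIC at posterior means
    md = chains.model_data
    params = chains.posterior_mean_params()
    b = chains.b_mean
    bet1 = np.concatenate([params.lmm.beta_sbp, params.lmm.delta_sbp])
    bet2 = np.concatenate([params.lmm.beta_dbp, params.lmm.delta_dbp])
    r1 = md.y1 - md.F1 @ bet1 - b[md.idx, 0] - b[md.idx, 1] * md.t
    r2 = md.y2 - md.F2 @ bet2 - b[md.idx, 2] - b[md.idx, 3] * md.t
    s2 = params.lmm.sigma_eps**2
    ll_hat = -0.5 * (
        md.t.size * (2 * _LOG_2PI + np.log(s2[0]) + np.log(s2[1]))
        + np.sum(r1**2) / s2[0]
        + np.sum(r2**2) / s2[1]
    )
    logh0c = params.hazard.log_baseline + float(
        md.US_mean @ params.hazard.gamma + params.hazard.rho @ md.m_ref
    )
    A1 = bet1[0] + md.U1 @ bet1[2:] + b[:, 0]
    B1 = bet1[1] + b[:, 1]
    A2 = bet2[0] + md.U2 @ bet2[2:] + b[:, 2]
    B2 = bet2[1] + b[:, 3]
    ll_hat += float(
        np.sum(
            _surv_loglik(md, A1, B1, A2, B2, logh0c, params.hazard.gamma, params.hazard.rho)
        )
    )
    d_bar = float(np.mean(-2.0 * chains.total_loglik))
    d_hat = -2.0 * ll_hat
    p_d = d_bar - d_hat
    dic = d_hat + 2.0 * p_d
    return {"dic": dic, "p_d": p_d, "waic": waic, "p_waic": p_waic, "lppd": lppd}


def dynamic_prediction(
    chains,
    history: pd.DataFrame,
    baseline_row,
    t_from: float,
    horizons,
    n_draws: int = 200,
    n_inner: int = 10,
    seed: int = 0,
    spec: DesignSpec | None = None,
) -> pd.DataFrame:
    """Conditional remission-free probability S(u | T > t, history).

    For each posterior draw (or for the fixed ``JointParams`` given), the
    subject's random effects are sampled by Metropolis steps targeting
    their conditional given the observed blood-pressure history and
    survival beyond ``t_from``; the conditional survival
    exp(-(Lambda(u) - Lambda(t))) is then averaged over draws.  Returns a
    frame with columns (horizon, mean, 2.5%, 97.5%).
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons < t_from):
        raise ConfigurationError("prediction horizons must be >= the landmark time")
    if len(history) < 1:
        raise ConfigurationError("subject needs at least one longitudinal record")
    spec = spec or (chains.spec if isinstance(chains, PosteriorChains) else defaults.default_design())
    rng = np.random.default_rng(seed)

    frame = pd.DataFrame([dict(baseline_row)])
    u1 = covariate_matrix(frame, spec.sbp_covariates)[0]
    u2 = covariate_matrix(frame, spec.dbp_covariates)[0]
    us = covariate_matrix(frame, spec.survival_covariates)[0]
    tt = history["time_months"].to_numpy(dtype=float)
    y1 = history["sbp_mmhg"].to_numpy(dtype=float)
    y2 = history["dbp_mmhg"].to_numpy(dtype=float)

    if isinstance(chains, PosteriorChains):
        pooled = {
            k: v.reshape(-1, *v.shape[2:]) for k, v in chains.draws.items()
        }
        n_avail = pooled["rho"].shape[0]
        take = np.linspace(0, n_avail - 1, min(n_draws, n_avail)).astype(int)

        def param_at(j):
            lmm = LMMParams(
                beta_sbp=pooled["beta_sbp"][j][:2],
                beta_dbp=pooled["beta_dbp"][j][:2],
                delta_sbp=pooled["beta_sbp"][j][2:],
                delta_dbp=pooled["beta_dbp"][j][2:],
                Sigma=pooled["Sigma"][j],
                sigma_eps=pooled["sigma_eps"][j],
            )
            hz = HazardParams(
                log_baseline=pooled["log_h0"][j],
                knots=chains.knots,
                gamma=pooled["gamma"][j],
                rho=pooled["rho"][j],
            )
            return JointParams(lmm=lmm, hazard=hz)

        param_list = [param_at(j) for j in take]
    else:
        chains.validate()
        param_list = [chains] * n_draws

    from .survival import cumulative_hazard

    surv_draws = np.empty((len(param_list), horizons.size))
    bcur = np.zeros(4)
    for m, par in enumerate(param_list):
        lmm, hz = par.lmm, par.hazard
        Sinv = np.linalg.inv(lmm.Sigma)
        cholS = np.linalg.cholesky(lmm.Sigma)
        base1 = lmm.beta_sbp[0] + u1 @ lmm.delta_sbp
        base2 = lmm.beta_dbp[0] + u2 @ lmm.delta_dbp
        s2 = lmm.sigma_eps**2

        def logtarget(bb):
            m1 = base1 + bb[0] + (lmm.beta_sbp[1] + bb[1]) * tt
            m2 = base2 + bb[2] + (lmm.beta_dbp[1] + bb[3]) * tt
            ll = -0.5 * (
                np.sum((y1 - m1) ** 2) / s2[0] + np.sum((y2 - m2) ** 2) / s2[1]
            )
            traj = np.array(
                [base1 + bb[0], lmm.beta_sbp[1] + bb[1], base2 + bb[2], lmm.beta_dbp[1] + bb[3]]
            )
            lam_t = cumulative_hazard(t_from, traj, us, hz) if t_from > 0 else 0.0
            return ll - lam_t - 0.5 * bb @ Sinv @ bb, traj, lam_t

        lt_cur, traj_cur, lam_cur = logtarget(bcur)
        for _ in range(n_inner):
            bprop = bcur + 0.6 * (cholS @ rng.standard_normal(4))
            lt_prop, traj_prop, lam_prop = logtarget(bprop)
            if np.log(rng.uniform()) < lt_prop - lt_cur:
                bcur, lt_cur, traj_cur, lam_cur = bprop, lt_prop, traj_prop, lam_prop
        lam_u = np.array(
            [cumulative_hazard(u, traj_cur, us, hz) for u in horizons]
        )
        surv_draws[m] = np.exp(-(lam_u - lam_cur))
    return pd.DataFrame(
        {
            "horizon": horizons,
            "mean": surv_draws.mean(axis=0),
            "2.5%": np.quantile(surv_draws, 0.025, axis=0),
            "97.5%": np.quantile(surv_draws, 0.975, axis=0),
        }
    )
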