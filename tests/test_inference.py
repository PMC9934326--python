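"""Priors, full conditionals, MCMC contracts, HR transforms, prediction, fit criteria."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bpjoint as bj
from bpjoint import defaults
from bpjoint.errors import ConfigurationError
from bpjoint.inference import (
    MCMCConfig,
    PRIOR_COEF_VAR,
    beta_full_conditional,
    draw_sigma,
    draw_sigma_eps2,
    run_mcmc,
)
from conftest import constant_hazard, zero_lmm


def tiny_joint_params(rng=None):
    """Small random but valid parameter point for density checks."""
    r = rng or np.random.default_rng(17)
    A = r.normal(size=(4, 4))
    lmm = bj.LMMParams(
        beta_sbp=r.normal(size=2),
        beta_dbp=r.normal(size=2),
        delta_sbp=r.normal(size=3),
        delta_dbp=r.normal(size=2),
        Sigma=A @ A.T + 0.5 * np.eye(4),
        sigma_eps=np.abs(r.normal(size=2)) + 0.5,
    )
    hazard = bj.HazardParams(
        log_baseline=r.normal(size=3),
        knots=np.array([0.0, 5.0, 15.0]),
        gamma=r.normal(size=2),
        rho=r.normal(size=4, scale=0.05),
    )
    sh = bj.ShrinkageHyper(tau=abs(r.normal()) + 0.2, psi=np.abs(r.normal(size=4)) + 0.2)
    return bj.JointParams(lmm=lmm, hazard=hazard, shrinkage=sh)


class TestLogPrior:
    def test_zero_coefficients_contribute_density_at_mode(self):
        p = tiny_joint_params()
        base = bj.log_prior(p)
        p2 = tiny_joint_params()
        p2.lmm.beta_sbp = p.lmm.beta_sbp.copy()
        assert isinstance(base, float) and np.isfinite(base)

    def test_moving_a_coefficient_from_zero_costs_quadratic(self):
        p = tiny_joint_params()
        p.lmm.beta_sbp[0] = 0.0
        base = bj.log_prior(p)
        k = 3.7
        p.lmm.beta_sbp[0] = k
        assert bj.log_prior(p) - base == pytest.approx(-(k**2) / (2 * PRIOR_COEF_VAR), abs=1e-10)

    def test_matches_term_by_term_oracle(self):
        """Independent scipy densities, summed term by term."""
        p = tiny_joint_params(np.random.default_rng(99))
        coefs = np.concatenate(
            [p.lmm.beta_sbp, p.lmm.beta_dbp, p.lmm.delta_sbp, p.lmm.delta_dbp,
             p.hazard.gamma, p.hazard.log_baseline]
        )
        oracle = sum(stats.norm.logpdf(c, 0, np.sqrt(1000.0)) for c in coefs)
        for s in range(4):
            oracle += stats.norm.logpdf(
                p.hazard.rho[s], 0, np.sqrt(p.shrinkage.tau * p.shrinkage.psi[s])
            )
        oracle += stats.invgamma.logpdf(p.shrinkage.tau, 0.1, scale=0.1)
        oracle += sum(stats.invgamma.logpdf(ps, 1.0, scale=0.01) for ps in p.shrinkage.psi)
        oracle += stats.invwishart.logpdf(p.lmm.Sigma, 5, np.eye(4))
        oracle += sum(
            stats.invgamma.logpdf(s2, 0.01, scale=0.01) for s2 in p.lmm.sigma_eps**2
        )
        assert bj.log_prior(p) == pytest.approx(oracle, abs=1e-10)

    def test_nonpositive_shrinkage_rejected(self):
        p = tiny_joint_params()
        p.shrinkage.tau = -1.0
        with pytest.raises(ConfigurationError):
            bj.log_prior(p)


class TestShrinkageConditionals:
    def test_tau_moments_at_zero_association(self):
        """rho=0: tau^-1 ~ Gamma(0.1 + 2, 0.1), mean 21 within 2%."""
        rng = np.random.default_rng(1)
        hyper = bj.ShrinkageHyper()
        draws = np.array(
            [1.0 / bj.sample_shrinkage(np.zeros(4), hyper, rng).tau for _ in range(100_000)]
        )
        assert np.mean(draws) == pytest.approx(2.1 / 0.1, rel=0.02)

    def test_psi_moments_at_zero_association(self):
        """rho=0: psi_s^-1 ~ Gamma(1.5, 0.01), mean 150 within 2%."""
        rng = np.random.default_rng(2)
        hyper = bj.ShrinkageHyper()
        draws = np.concatenate(
            [1.0 / bj.sample_shrinkage(np.zeros(4), hyper, rng).psi for _ in range(25_000)]
        )
        assert np.mean(draws) == pytest.approx(1.5 / 0.01, rel=0.02)

    def test_reproducible_for_fixed_rng(self):
        a = bj.sample_shrinkage(np.ones(4) * 0.1, bj.ShrinkageHyper(), np.random.default_rng(5))
        b = bj.sample_shrinkage(np.ones(4) * 0.1, bj.ShrinkageHyper(), np.random.default_rng(5))
        assert a.tau == b.tau and np.array_equal(a.psi, b.psi)


class TestConjugateBlocks:
    """Gibbs full-conditional moment checks against analytic distributions."""

    def test_fixed_effect_conditional_moments(self):
        rng = np.random.default_rng(3)
        n, p = 120, 4
        F = rng.normal(size=(n, p))
        ytil = rng.normal(size=n)
        s2 = 2.3
        mean, chol = beta_full_conditional(F, F.T @ F, ytil, s2)
        # independent derivation of the Bayesian linear-model posterior
        prec = F.T @ F / s2 + np.eye(p) / 1000.0
        cov = np.linalg.inv(prec)
        assert np.allclose(mean, cov @ F.T @ ytil / s2, atol=1e-10)
        draws = mean + np.linalg.solve(chol.T, rng.standard_normal((p, 40_000))).T
        assert np.allclose(np.cov(draws.T), cov, atol=4 * np.abs(cov).max() / np.sqrt(40_000))

    def test_residual_variance_conditional_moments(self):
        rng = np.random.default_rng(4)
        ssr, n = 480.0, 200
        draws = np.array([draw_sigma_eps2(ssr, n, rng) for _ in range(50_000)])
        a, scale = 0.01 + n / 2, 0.01 + ssr / 2
        assert np.mean(draws) == pytest.approx(scale / (a - 1), rel=0.02)
        assert np.var(draws) == pytest.approx(scale**2 / ((a - 1) ** 2 * (a - 2)), rel=0.1)

    def test_covariance_conditional_moments(self):
        rng = np.random.default_rng(6)
        b = rng.normal(size=(150, 4)) @ np.diag([3.0, 0.5, 2.0, 0.4])
        nu = 5 + 150
        scale = np.eye(4) + b.T @ b
        expected_mean = scale / (nu - 4 - 1)
        draws = np.mean([draw_sigma(b, rng) for _ in range(4000)], axis=0)
        assert np.allclose(draws, expected_mean, rtol=0.08, atol=0.02)


class TestLogPosterior:
    def _tiny_tables(self):
        cfg = bj.CohortConfig(n_subjects=6, visit_schedule=(0.0, 2.0, 5.0), seed=8)
        return bj.generate_cohort(cfg)

    def test_equals_sum_of_component_oracles(self, design):
        cohort, lng, surv, truth = self._tiny_tables()
        rng = np.random.default_rng(12)
        b = rng.normal(size=(len(cohort), 4))
        from bpjoint.design import covariate_matrix
        from bpjoint.survival import trajectory_coefficients

        ll = bj.loglik_longitudinal(truth.lmm, b, lng, cohort, design)
        u1 = covariate_matrix(cohort, design.sbp_covariates)
        u2 = covariate_matrix(cohort, design.dbp_covariates)
        us = covariate_matrix(cohort, design.survival_covariates)
        traj = trajectory_coefficients(truth.lmm, b, u1, u2)
        sv = surv.set_index("id")
        for k, sid in enumerate(cohort["id"]):
            ll += bj.loglik_event(
                float(sv.loc[sid, "time_months"]), int(sv.loc[sid, "event"]),
                traj[k], us[k], truth.hazard,
            )
        ll += stats.multivariate_normal.logpdf(b, np.zeros(4), truth.lmm.Sigma).sum()
        ll += bj.log_prior(truth)
        got = bj.log_posterior(truth, b, cohort, lng, surv, design)
        assert got == pytest.approx(ll, abs=1e-8)

    def test_moving_observation_from_mean_decreases_density(self, design):
        cohort, lng, surv, truth = self._tiny_tables()
        b = np.zeros((len(cohort), 4))
        base = bj.log_posterior(truth, b, cohort, lng, surv, design)
        worse = lng.copy()
        worse.loc[0, "sbp_mmhg"] += 25.0
        # shifting an observation further from its mean can only reduce the density
        lower = bj.log_posterior(truth, b, cohort, worse, surv, design)
        even_worse = lng.copy()
        even_worse.loc[0, "sbp_mmhg"] += 50.0
        lowest = bj.log_posterior(truth, b, cohort, even_worse, surv, design)
        assert lowest < lower < base or lower < base


@pytest.fixture(scope="module")
def tiny_fit():
    cfg = bj.CohortConfig(n_subjects=25, visit_schedule=tuple(float(t) for t in range(0, 30, 2)), seed=10)
    cohort, lng, surv, truth = bj.generate_cohort(cfg)
    mcfg = MCMCConfig(n_chains=2, n_iter=300, burn_in=150, thin=3, seed=21, n_intervals=3)
    return cohort, lng, surv, run_mcmc(cohort, lng, surv, mcfg), mcfg


class TestRunMcmc:

    def test_same_seed_gives_identical_draws(self, tiny_fit):
        cohort, lng, surv, chains, mcfg = tiny_fit
        again = run_mcmc(cohort, lng, surv, mcfg)
        for key in chains.draws:
            assert np.array_equal(chains.draws[key], again.draws[key])

    def test_summary_invariants(self, tiny_fit):
        *_, chains, _ = tiny_fit
        s = chains.summary()
        assert (s["ci_2.5%"] <= s["post_mean"] + 1e-12).all()
        assert (s["post_mean"] <= s["ci_97.5%"] + 1e-12).all()
        assert (s["rhat"] > 0.9).all()
        assert (s["ess"] > 0).all()
        # residual SDs and random-effect SDs are positive in every draw
        assert np.all(chains.draws["sigma_eps"] > 0)
        assert np.all(chains.draws["Sigma"][..., [0, 1, 2, 3], [0, 1, 2, 3]] > 0)

    def test_inconsistent_ids_rejected(self, tiny_fit):
        from bpjoint.errors import SchemaError

        cohort, lng, surv, _, mcfg = tiny_fit
        with pytest.raises(SchemaError):
            run_mcmc(cohort, lng, surv.assign(id=surv["id"] + 5), mcfg)

    def test_all_censored_rejected(self, tiny_fit):
        cohort, lng, surv, _, mcfg = tiny_fit
        with pytest.raises(ConfigurationError, match="identifiab"):
            run_mcmc(cohort, lng, surv.assign(event=0), mcfg)

    def test_zero_association_matches_separate_mixed_model(self):
        """With rho fixed at 0 the longitudinal block is a plain bivariate
        mixed model; posterior means agree with a frequentist LMM fit."""
        import statsmodels.formula.api as smf

        truth = bj.default_truth()
        truth.hazard.rho[:] = 0.0
        truth.hazard.log_baseline[:] = np.log(0.05)
        cfg = bj.CohortConfig(n_subjects=120, seed=14)
        cohort, lng, surv, _ = bj.generate_cohort(cfg, truth)
        mcfg = MCMCConfig(
            n_chains=2, n_iter=1200, burn_in=600, thin=3, seed=33,
            fix_rho=np.zeros(4),
        )
        chains = run_mcmc(cohort, lng, surv, mcfg)
        s = chains.summary()
        data = lng.merge(cohort, on="id")
        lmm = smf.mixedlm(
            "sbp_mmhg ~ time_months + age + dm", data, groups=data["id"],
            re_formula="~time_months",
        ).fit()
        for name, key in (("time_months", "sbp:time"), ("age", "sbp:age"), ("dm", "sbp:dm")):
            se = np.sqrt(lmm.bse[name] ** 2 + s.loc[key, "post_sd"] ** 2)
            assert abs(lmm.params[name] - s.loc[key, "post_mean"]) < 4 * se


class TestHazardRatioSummary:
    def test_reported_association_transform(self):
        out = bj.hazard_ratio_summary(-0.1128)
        assert round(out["hr"], 2) == 0.89
        assert out["percent_change"] == pytest.approx(10.67, abs=0.005)
        assert out["direction"] == "decrease"

    def test_zero_coefficient(self):
        out = bj.hazard_ratio_summary(0.0)
        assert out["hr"] == 1.0 and out["percent_change"] == 0.0

    def test_draws_give_interval(self):
        rng = np.random.default_rng(0)
        out = bj.hazard_ratio_summary(rng.normal(0.3, 0.05, size=4000))
        assert out["hr_2.5%"] < out["hr"] < out["hr_97.5%"]
        assert out["direction"] == "increase"


class TestDynamicPrediction:
    def _setup(self):
        params = bj.JointParams(
            lmm=zero_lmm(14, 13), hazard=constant_hazard(0.08, gamma=np.zeros(6))
        )
        params.lmm.Sigma = np.eye(4)
        params.lmm.sigma_eps = np.array([5.0, 5.0])
        row = {
            "id": 1, "sex": "female", "residence": "rural", "age": 50.0,
            "bcl": 0, "gbl": 0, "bun": 0, "creatinine": 0, "calcium": 0,
            "sodium": 0, "potassium": 0, "chlorine": 0, "hemoglobin": 0,
            "dm": 0, "ckd": 0, "stroke": 0, "hiv": 0,
            "regimen": "monotherapy", "drug_type": "enalapril",
        }
        history = pd.DataFrame(
            {"id": [1, 1], "time_months": [0.0, 3.0], "sbp_mmhg": [1.0, -1.0], "dbp_mmhg": [0.5, 0.0]}
        )
        return params, row, history

    def test_probability_one_at_landmark(self):
        params, row, history = self._setup()
        pred = bj.dynamic_prediction(params, history, row, 5.0, [5.0], n_draws=20, seed=1)
        assert pred["mean"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_horizon_and_matches_exponential(self):
        params, row, history = self._setup()
        grid = [5.0, 8.0, 12.0, 20.0]
        pred = bj.dynamic_prediction(params, history, row, 5.0, grid, n_draws=30, seed=2)
        assert (np.diff(pred["mean"]) <= 1e-12).all()
        # association zero: conditional survival is exp(-h0 (u - t)) exactly
        expected = np.exp(-0.08 * (np.array(grid) - 5.0))
        assert np.allclose(pred["mean"], expected, atol=1e-9)

    def test_horizon_before_landmark_rejected(self):
        params, row, history = self._setup()
        with pytest.raises(ConfigurationError):
            bj.dynamic_prediction(params, history, row, 5.0, [4.0], seed=0)


class TestModelFitCriteria:
    def test_waic_additive_over_duplicated_subjects(self):
        cfg = bj.CohortConfig(n_subjects=12, visit_schedule=(0.0, 3.0, 6.0, 9.0), seed=15)
        cohort, lng, surv, _ = bj.generate_cohort(cfg)
        mcfg = MCMCConfig(n_chains=1, n_iter=300, burn_in=150, thin=3, seed=9, n_intervals=2)
        c1 = run_mcmc(cohort, lng, surv, mcfg)
        w1 = bj.model_fit_criteria(c1)
        # duplicate every subject under fresh ids
        c2_cohort = pd.concat([cohort, cohort.assign(id=cohort["id"] + 1000)], ignore_index=True)
        c2_lng = pd.concat([lng, lng.assign(id=lng["id"] + 1000)], ignore_index=True)
        c2_surv = pd.concat([surv, surv.assign(id=surv["id"] + 1000)], ignore_index=True)
        c2 = run_mcmc(c2_cohort, c2_lng, c2_surv, mcfg)
        w2 = bj.model_fit_criteria(c2)
        assert w2["waic"] == pytest.approx(2 * w1["waic"], rel=0.15)

    def test_single_draw_dic_reduces_to_deviance(self):
        cfg = bj.CohortConfig(n_subjects=10, visit_schedule=(0.0, 4.0, 8.0), seed=16)
        cohort, lng, surv, _ = bj.generate_cohort(cfg)
        mcfg = MCMCConfig(n_chains=1, n_iter=101, burn_in=100, thin=1, seed=3, n_intervals=2)
        chains = run_mcmc(cohort, lng, surv, mcfg)
        out = bj.model_fit_criteria(chains)
        assert out["p_d"] == pytest.approx(0.0, abs=1e-6)
        assert out["dic"] == pytest.approx(-2 * chains.total_loglik.ravel()[0], abs=1e-6)
        assert out["p_waic"] == 0.0
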