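"""Synthetic cohort generator: margins, trajectories, event times, determinism."""
import numpy as np
import pytest

import bpjoint as bj
from bpjoint import defaults
from bpjoint.errors import ConfigurationError
from bpjoint.simulate import threshold_remission_times
from conftest import constant_hazard, zero_lmm


def _binomial_ci(p, n, z=2.576):
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


class TestBaseline:
    def test_male_fraction_within_binomial_interval(self):
        cfg = bj.CohortConfig(n_subjects=301, seed=12)
        cohort = bj.sample_baseline(cfg)
        frac = (cohort["sex"] == "male").mean()
        lo, hi = _binomial_ci(0.508, 301)
        assert lo <= frac <= hi

    def test_empty_cohort_allowed(self):
        cohort = bj.sample_baseline(bj.CohortConfig(n_subjects=0, seed=0))
        assert len(cohort) == 0

    def test_dm_fraction_at_large_n(self):
        cfg = bj.CohortConfig(n_subjects=10_000, seed=5)
        cohort = bj.sample_baseline(cfg)
        se = np.sqrt(0.276 * (1 - 0.276) / 10_000)
        assert abs(cohort["dm"].mean() - 83 / 301) < 2.8 * se

    def test_age_respects_inclusion_bound(self):
        cohort = bj.sample_baseline(bj.CohortConfig(n_subjects=2000, seed=9))
        assert cohort["age"].min() >= 15.0

    def test_invalid_probability_vector_names_covariate(self):
        cfg = bj.CohortConfig(seed=0)
        cfg.covariate_frequencies["sex"] = {"female": 0.6, "male": 0.6}
        with pytest.raises(ConfigurationError, match="sex"):
            bj.sample_baseline(cfg)

    def test_bad_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            bj.CohortConfig(visit_schedule=(0.0, 2.0, 1.0)).validate()
        with pytest.raises(ConfigurationError):
            bj.CohortConfig(visit_schedule=(0.0, 40.0), admin_censor_time=30.0).validate()


class TestRandomEffects:
    def test_zero_covariance_gives_zero_effects(self):
        b = bj.sample_random_effects(50, np.zeros((4, 4)), 1)
        assert np.all(b == 0.0)

    def test_reported_intercept_correlation_recovered(self, truth):
        b = bj.sample_random_effects(50_000, truth.lmm.Sigma, 3)
        corr = np.corrcoef(b[:, 0], b[:, 2])[0, 1]
        assert corr == pytest.approx(0.7720, abs=0.01)

    def test_identity_covariance_off_diagonals_near_zero(self):
        b = bj.sample_random_effects(50_000, np.eye(4), 11)
        corr = np.corrcoef(b.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.02)

    def test_empirical_covariance_converges_entrywise(self, truth):
        """|empirical - input| < 3 SE for every entry at n = 50,000."""
        n = 50_000
        b = bj.sample_random_effects(n, truth.lmm.Sigma, 21)
        emp = np.cov(b.T)
        S = truth.lmm.Sigma
        for i in range(4):
            for j in range(4):
                se = np.sqrt((S[i, i] * S[j, j] + S[i, j] ** 2) / n)
                assert abs(emp[i, j] - S[i, j]) < 3 * se

    def test_non_pd_covariance_rejected(self):
        bad = np.eye(4)
        bad[0, 0] = -1.0
        with pytest.raises(ConfigurationError):
            bj.sample_random_effects(10, bad, 0)


class TestTrajectories:
    def test_zero_residual_sd_gives_exact_trajectories(self, truth, design):
        cfg = bj.CohortConfig(n_subjects=5, seed=2)
        cohort = bj.sample_baseline(cfg)
        b = bj.sample_random_effects(5, truth.lmm.Sigma, 3)
        noiseless = truth.copy()
        noiseless.lmm.sigma_eps = np.zeros(2)
        obs, true = bj.sample_trajectories(
            cohort, b, noiseless, cfg.visit_schedule, design, 4
        )
        assert np.allclose(obs["sbp_mmhg"], true["sbp_mmhg"])
        assert np.allclose(obs["dbp_mmhg"], true["dbp_mmhg"])

    def test_empty_schedule_rejected(self, truth, design):
        cohort = bj.sample_baseline(bj.CohortConfig(n_subjects=2, seed=0))
        with pytest.raises(ConfigurationError):
            bj.sample_trajectories(cohort, np.zeros((2, 4)), truth, [], design)


class TestEventTimes:
    def test_exponential_closed_form(self):
        truth = bj.JointParams(lmm=zero_lmm(), hazard=constant_hazard(0.1))
        t, event = bj.sample_event_time(np.zeros(4), np.empty(0), truth, 0.5, 1e6)
        assert event == 1
        assert t == pytest.approx(np.log(2) / 0.1, abs=1e-6)

    def test_exponential_mean_over_many_draws(self):
        truth = bj.JointParams(lmm=zero_lmm(), hazard=constant_hazard(0.1))
        rng = np.random.default_rng(8)
        draws = [
            bj.sample_event_time(np.zeros(4), np.empty(0), truth, u, 1e6)[0]
            for u in rng.uniform(size=5000)
        ]
        assert np.mean(draws) == pytest.approx(10.0, abs=0.4)

    def test_administrative_censoring_rule(self):
        truth = bj.JointParams(lmm=zero_lmm(), hazard=constant_hazard(0.01))
        # Lambda(30) = 0.3; any u with -log(u) > 0.3 is censored at 30
        t, event = bj.sample_event_time(np.zeros(4), np.empty(0), truth, 0.5, 30.0)
        assert (t, event) == (30.0, 0)

    def test_invalid_uniform_rejected(self):
        truth = bj.JointParams(lmm=zero_lmm(), hazard=constant_hazard(0.1))
        with pytest.raises(ConfigurationError):
            bj.sample_event_time(np.zeros(4), np.empty(0), truth, 0.0, 30.0)


class TestGenerateCohort:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        a = bj.generate_cohort(bj.CohortConfig(n_subjects=15, seed=77))
        b = bj.generate_cohort(bj.CohortConfig(n_subjects=15, seed=77))
        for x, y in zip(a[:3], b[:3]):
            da, db = tmp_path / "a.csv", tmp_path / "b.csv"
            x.to_csv(da, index=False)
            y.to_csv(db, index=False)
            assert da.read_bytes() == db.read_bytes()

    def test_referential_integrity_default_cohort(self, small_cohort):
        _, cohort, lng, surv, _ = small_cohort
        assert len(cohort) > 0 and len(lng) > 0 and len(surv) > 0
        assert set(lng["id"]) <= set(cohort["id"])
        assert set(surv["id"]) == set(cohort["id"])
        exit_times = surv.set_index("id")["time_months"]
        assert np.all(
            lng["time_months"].to_numpy() <= exit_times.loc[lng["id"]].to_numpy()
        )

    def test_censoring_fraction_matches_target_survival(self):
        """Association and covariates off, h0 with S(30)=0.2: 20% censored."""
        h0 = -np.log(0.2) / 30.0
        truth = bj.JointParams(
            lmm=zero_lmm(14, 13), hazard=constant_hazard(h0, gamma=np.zeros(6))
        )
        truth.lmm.Sigma = np.eye(4) * 1e-12
        truth.lmm.sigma_eps = np.array([1.0, 1.0])
        cfg = bj.CohortConfig(n_subjects=2000, seed=31)
        _, _, surv, _ = bj.generate_cohort(cfg, truth)
        cens = 1.0 - surv["event"].mean()
        assert cens == pytest.approx(0.2, abs=0.02)

    def test_km_tracks_analytic_baseline_without_association(self):
        """Zero association: empirical KM within 0.03 sup-distance of exp(-h0 t)."""
        h0 = 0.05
        truth = bj.JointParams(
            lmm=zero_lmm(14, 13), hazard=constant_hazard(h0, gamma=np.zeros(6))
        )
        truth.lmm.Sigma = np.eye(4) * 1e-12
        truth.lmm.sigma_eps = np.array([1.0, 1.0])
        cfg = bj.CohortConfig(n_subjects=5000, seed=13)
        _, _, surv, _ = bj.generate_cohort(cfg, truth)
        km = bj.km_estimate(surv["time_months"], surv["event"])
        inside = km.times <= 29.9
        sup = np.max(np.abs(km.survival[inside] - np.exp(-h0 * km.times[inside])))
        assert sup < 0.03

    def test_default_cohort_matches_study_margins(self):
        """Default generator: event rate and KM median near the study's."""
        cohort, lng, surv, _ = bj.generate_cohort(bj.CohortConfig(n_subjects=301, seed=1))
        assert surv["event"].mean() == pytest.approx(0.807, abs=0.06)
        km = bj.km_estimate(surv["time_months"], surv["event"])
        assert abs(km.median - 11.0) <= 3.0
        # observed baseline pressures near the reported 152.18 / 92.79 mmHg
        first = lng[lng["time_months"] == 0.0]
        assert abs(first["sbp_mmhg"].mean() - 152.18) < 6.0
        assert abs(first["dbp_mmhg"].mean() - 92.79) < 4.0

    def test_threshold_remission_diagnostic(self, small_cohort):
        _, _, lng, _, _ = small_cohort
        flagged = threshold_remission_times(lng)
        assert (flagged >= 0).all()
        sub = lng[lng["id"].isin(flagged.index)]
        merged = sub.merge(flagged.rename("flag_time"), left_on="id", right_index=True)
        at_flag = merged[merged["time_months"] == merged["flag_time"]]
        assert ((at_flag["sbp_mmhg"] < 140) & (at_flag["dbp_mmhg"] < 90)).all()
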