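"""Synthetic cohort generator: calibration, closed-form event-time
distributions, observation-scheme rules, determinism."""

import numpy as np
import pytest
from scipy import stats

import isletprog as ip
from isletprog.datamodel import OGTT_VARIABLES
from isletprog.io import write_long_table
from isletprog.multistate import PiecewiseConstantHazard
from isletprog.simulate import (
    SimulationConfig,
    sample_age_at_gada,
    sample_baseline,
    sample_event_time_inverse_cdf,
    simulate_cohort,
    simulate_trajectories,
    simulate_transitions,
    DominatingRateOverflow,
)
from conftest import make_baseline, single_transition_config


class TestBaselineSampling:
    def test_degenerate_frequency_all_female(self):
        cfg = ip.default_config(n_subjects=0)
        cfg.covariate_freqs["female"] = 1.0
        rng = np.random.default_rng(0)
        assert all(sample_baseline(cfg, rng).sex == "female" for _ in range(50))

    def test_marginals_match_study_frequencies(self):
        """Sampled covariate frequencies converge to the cohort-table values."""
        cfg = ip.default_config(n_subjects=0)
        rng = np.random.default_rng(1)
        n = 5000
        draws = [sample_baseline(cfg, rng) for _ in range(n)]
        for value, p in [
            (np.mean([d.sex == "female" for d in draws]), 0.459),
            (np.mean([d.fdr for d in draws]), 0.174),
            (np.mean([d.dq_group == "DQ2/8" for d in draws]), 0.488),
            (np.mean([d.dq_group == "DQ8/X" for d in draws]), 0.296),
            (np.mean([d.dq_group == "DQ2/X" for d in draws]), 0.216),
        ]:
            assert abs(value - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_age_median_and_iqr(self):
        cfg = ip.default_config(n_subjects=0)
        ages = sample_age_at_gada(cfg, np.random.default_rng(2), 5000)
        q25, q50, q75 = np.percentile(ages, [25, 50, 75])
        assert q50 == pytest.approx(5.1, abs=0.3)
        assert q25 == pytest.approx(2.4, abs=0.2)
        assert q75 == pytest.approx(9.0, abs=0.5)
        assert ages.min() > 0

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimulationConfig(n_subjects=1, covariate_freqs={
                "female": 1.4, "fdr": 0.1, "dq2_8": 0.5, "dq8_x": 0.3, "dq2_x": 0.2})
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(n_subjects=1, covariate_freqs={
                "female": 0.5, "fdr": 0.1, "dq2_8": 0.5, "dq8_x": 0.3, "dq2_x": 0.3})


class TestTrajectories:
    def test_zero_sigma_b_gives_population_mean(self, baseline):
        cfg = ip.default_config(n_subjects=0)
        cfg.sigma_b = np.zeros_like(cfg.sigma_b)
        traj = simulate_trajectories(baseline, cfg, np.random.default_rng(3))
        t = np.linspace(0, 10, 7)
        for spec in cfg.specs:
            mean = spec.design(t) @ cfg.beta[spec.variable]
            np.testing.assert_allclose(traj.value(spec.variable, t), mean, atol=1e-12)

    def test_pointwise_variance_matches_gaussian_formula(self, baseline):
        """var m_j(t) across subjects equals z(t)' Sigma_b z(t)."""
        cfg = ip.default_config(n_subjects=0)
        rng = np.random.default_rng(4)
        n = 10_000
        var = "gada_z"
        t = np.asarray([2.5])
        vals = np.empty(n)
        for i in range(n):
            traj = simulate_trajectories(baseline, cfg, rng)
            vals[i] = traj.value(var, t)[0]
        spec = next(s for s in cfg.specs if s.variable == var)
        z = spec.design(t)[0, list(spec.random_terms)]
        sl = cfg.rand_slices[var]
        expected = float(z @ cfg.sigma_b[sl, sl] @ z)
        mc_sd = expected * np.sqrt(2.0 / n)
        assert abs(np.var(vals) - expected) < 3 * mc_sd

    def test_same_seed_identical_trajectories(self, baseline):
        cfg = ip.default_config(n_subjects=0)
        t = np.linspace(0, 12, 20)
        a = simulate_trajectories(baseline, cfg, np.random.default_rng(5)).value("hba1c", t)
        b = simulate_trajectories(baseline, cfg, np.random.default_rng(5)).value("hba1c", t)
        np.testing.assert_array_equal(a, b)

    def test_non_psd_sigma_b_rejected(self):
        cfg = ip.default_config(n_subjects=1)
        bad = np.asarray(cfg.sigma_b).copy()
        bad[0, 1] = bad[1, 0] = 10.0
        with pytest.raises(ValueError, match="semidefinite"):
            SimulationConfig(n_subjects=1, sigma_b=bad)


class TestTransitionSampling:
    def test_zero_hazard_everyone_censored(self, baseline):
        cfg = single_transition_config(levels=(0.0,))
        traj = simulate_trajectories(baseline, cfg, np.random.default_rng(6))
        recs = simulate_transitions(baseline, traj, cfg, np.random.default_rng(6), censor_time=8.0)
        assert len(recs) == 1 and recs[0].state == 1 and recs[0].next_state is None
        assert recs[0].exit_time == 8.0

    def test_constant_hazard_exponential_survival(self, baseline):
        """Survival in state 1 at t=5 with h=0.2/yr equals exp(-1)."""
        cfg = single_transition_config(levels=(0.2,))
        rng = np.random.default_rng(7)
        n = 4000
        surv = 0
        traj = simulate_trajectories(baseline, cfg, rng)  # no covariates: shared
        for _ in range(n):
            recs = simulate_transitions(baseline, traj, cfg, rng, censor_time=10.0)
            t_exit = recs[0].exit_time if recs[0].next_state is not None else 10.0
            surv += t_exit > 5.0
        p = np.exp(-1.0)
        assert abs(surv / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_competing_hazards_destination_fractions(self, baseline):
        """lam12=0.3, lam14=0.1: 75% of first moves go to state 2."""
        cfg = SimulationConfig(
            n_subjects=0,
            transition_coefs={(1, 2): (), (1, 4): ()},
            baseline_hazards={(1, 2): ((), (0.3,)), (1, 4): ((), (0.1,))},
        )
        rng = np.random.default_rng(8)
        traj = simulate_trajectories(baseline, cfg, rng)
        to2 = n_events = 0
        for _ in range(3000):
            recs = simulate_transitions(baseline, traj, cfg, rng, censor_time=30.0)
            if recs[0].next_state is not None:
                n_events += 1
                to2 += recs[0].next_state == 2
        assert n_events > 2900  # censoring at 30y with rate 0.4 is negligible
        assert abs(to2 / n_events - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n_events)

    def test_thinning_matches_inverse_cdf_sampler(self, baseline):
        """Distributional equality with the closed-form sampler for a
        piecewise-constant hazard (two-sample Kolmogorov-Smirnov)."""
        levels, cuts = (0.25, 0.6), (2.0,)
        cfg = single_transition_config(levels=levels, cuts=cuts)
        rng = np.random.default_rng(9)
        traj = simulate_trajectories(baseline, cfg, rng)
        n = 2000
        thin = np.empty(n)
        for i in range(n):
            recs = simulate_transitions(baseline, traj, cfg, rng, censor_time=50.0)
            thin[i] = recs[0].exit_time if recs[0].next_state is not None else 50.0
        hz = PiecewiseConstantHazard(cuts, levels)
        inv = np.asarray([sample_event_time_inverse_cdf(hz, rng, 50.0) for _ in range(n)])
        assert stats.ks_2samp(thin, inv).pvalue > 0.01

    def test_overflow_reports_linear_predictor(self, baseline):
        cfg = single_transition_config(levels=(0.1,), roster=(("hba1c", 500.0),))
        traj = simulate_trajectories(baseline, cfg, np.random.default_rng(10))
        with pytest.raises(DominatingRateOverflow, match="max lp"):
            simulate_transitions(baseline, traj, cfg, np.random.default_rng(10), censor_time=10.0)


class TestObservationScheme:
    def test_no_ogtt_while_single_gada(self, small_cohort):
        """OGTT requires multiple autoantibodies: no OGTT record may fall in
        an observed state-1 sojourn, and none before age 3."""
        for subj in small_cohort:
            state1 = [(r.entry_time, r.exit_time) for r in subj.path if r.state == 1]
            for rec in subj.longitudinal:
                if rec.variable in OGTT_VARIABLES:
                    assert subj.baseline.age_at_gada + rec.time >= 3.0
                    for a, b in state1:
                        assert not (a <= rec.time < b)

    def test_censored_in_state1_has_zero_ogtt_records(self, small_cohort):
        lone = [s for s in small_cohort if all(r.state == 1 for r in s.path)]
        assert lone, "fixture should contain never-progressing subjects"
        for subj in lone:
            assert not any(r.variable in OGTT_VARIABLES for r in subj.longitudinal)

    def test_no_records_after_diabetes_onset(self, small_cohort):
        for subj in small_cohort:
            t4 = [r.exit_time for r in subj.path if r.next_state == 4]
            if t4:
                assert all(rec.time <= t4[0] + 1e-9 for rec in subj.longitudinal)

    def test_zero_noise_observations_equal_latent(self):
        cfg = ip.default_config(n_subjects=5, seed=13)
        cfg.sigma = {k: 0.0 for k in cfg.sigma}
        cohort = simulate_cohort(cfg)
        for subj in cohort:
            for rec in subj.longitudinal:
                latent = subj.latent.trajectories.value(rec.variable, rec.time)[0]
                assert rec.value == pytest.approx(latent, abs=1e-12)


class TestCohortAssembly:
    def test_empty_cohort(self):
        assert len(simulate_cohort(ip.default_config(n_subjects=0))) == 0

    def test_study_sized_default(self):
        assert ip.default_config().n_subjects == 379

    def test_same_seed_byte_identical_tables(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_long_table(simulate_cohort(ip.default_config(n_subjects=10, seed=3)), a)
        write_long_table(simulate_cohort(ip.default_config(n_subjects=10, seed=3)), b)
        for f in ("measurements.csv", "events.csv", "baseline.csv"):
            assert (a / f).read_bytes() == (b / f).read_bytes()

    def test_cohort_is_valid_and_metadata_carries_truth(self, small_cohort):
        assert ip.validate_cohort(small_cohort) == []
        assert small_cohort.metadata["seed"] == 7
        assert "transition_coefs" in small_cohort.metadata


def test_kaplan_meier_cross_check(baseline):
    """Independent oracle: lifelines' KM estimate on simulated single-transition
    data reproduces the exponential survival curve."""
    lifelines = pytest.importorskip("lifelines")
    cfg = single_transition_config(levels=(0.3,))
    rng = np.random.default_rng(11)
    traj = simulate_trajectories(baseline, cfg, rng)
    T, E = [], []
    for _ in range(2000):
        recs = simulate_transitions(baseline, traj, cfg, rng, censor_time=6.0)
        ev = recs[0].next_state is not None
        T.append(recs[0].exit_time)
        E.append(ev)
    km = lifelines.KaplanMeierFitter().fit(T, E)
    for t in (1.0, 3.0, 5.0):
        p = np.exp(-0.3 * t)
        assert float(km.predict(t)) == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 2000) + 0.01)
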