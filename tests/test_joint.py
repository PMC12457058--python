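"""Joint likelihood integration, posterior sampling, and dynamic prediction."""

import numpy as np
import pytest
from scipy import stats

import isletprog as ip
from isletprog.datamodel import Cohort, LongitudinalRecord, StateRecord, Subject
from isletprog.joint import (
    IntegrationSettings,
    SubjectHistory,
    fit_joint,
    joint_log_likelihood,
    predict_occupancy,
    predict_trajectory,
    sample_posterior_random_effects,
    update_prediction,
)
from isletprog.multistate import CovariatePath, PiecewiseConstantHazard, TransitionModel, transition_probability_matrix
from isletprog.simulate import SimulationConfig, simulate_trajectories, simulate_transitions
from isletprog.splines import LongitudinalSpec, SplineSpec
from conftest import history_in_state1, make_baseline, toy_1d_joint_fit, toy_1d_longitudinal_fit


def _toy_records(times=(0.0, 0.5, 1.0, 2.0), offset=0.4, beta=(5.0, 0.1)):
    return [LongitudinalRecord("hba1c", t, beta[0] + beta[1] * t + offset) for t in times]


# ---------------------------------------------------------------------------
# joint_log_likelihood
# ---------------------------------------------------------------------------

class TestJointLogLikelihood:
    def test_degenerate_prior_decomposes(self):
        """Sigma_b = 0: marginal = fixed-effect Gaussian density + multistate
        log-likelihood at the population mean trajectory."""
        fit = toy_1d_joint_fit(alpha=0.8, h0=0.05, tau2=0.0, sigma=0.3)
        recs = _toy_records()
        hist = history_in_state1(make_baseline(), recs, 3.0)
        ll = joint_log_likelihood(fit, hist, IntegrationSettings(method="laplace"))
        mean = np.array([5.0 + 0.1 * r.time for r in recs])
        y = np.array([r.value for r in recs])
        ll_long = stats.norm.logpdf(y, mean, 0.3).sum()
        # survival in state 1 to s=3 under h(t) = h0 exp(0.8 (m(t) - 5))
        grid = np.linspace(0, 3, 3001)
        rate = 0.05 * np.exp(0.8 * (5.0 + 0.1 * grid - 5.0))
        ll_ms = -np.trapezoid(rate, grid)
        assert ll == pytest.approx(ll_long + ll_ms, abs=1e-4)

    def test_laplace_gh_mc_agree_on_1d_toy(self):
        fit = toy_1d_joint_fit(alpha=0.8, h0=0.05)
        hist = history_in_state1(make_baseline(), _toy_records(), 3.0)
        ll_lap = joint_log_likelihood(fit, hist, IntegrationSettings(method="laplace"))
        ll_gh = joint_log_likelihood(fit, hist, IntegrationSettings(method="gh", n_nodes=30))
        ll_mc = joint_log_likelihood(fit, hist, IntegrationSettings(method="mc", n_draws=400_000, seed=4))
        assert ll_lap == pytest.approx(ll_gh, abs=1e-2)
        assert ll_lap == pytest.approx(ll_mc, abs=1e-2)

    def test_likelihood_peaks_near_truth_variance(self):
        """Average marginal log-likelihood over simulated subjects is higher
        at the generating tau2 than at badly mis-scaled values."""
        rng = np.random.default_rng(5)
        tau2, sigma = 0.25, 0.3
        hists = []
        for _ in range(20):
            b = rng.normal(0, np.sqrt(tau2))
            recs = [
                LongitudinalRecord("hba1c", t, 5.0 + 0.1 * t + b + rng.normal(0, sigma))
                for t in np.linspace(0, 3, 7)
            ]
            hists.append(history_in_state1(make_baseline(), recs, 3.0))

        def total(tau2_val):
            fit = toy_1d_joint_fit(alpha=0.0, h0=0.05, tau2=tau2_val, sigma=sigma)
            return sum(joint_log_likelihood(fit, h, IntegrationSettings()) for h in hists)

        assert total(tau2) > total(tau2 * 6)
        assert total(tau2) > total(tau2 / 6)


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------

class TestPosteriorSampling:
    def test_zero_hazard_matches_closed_form_gaussian(self):
        """With no survival weighting the draws are the exact longitudinal
        posterior (KS test at n=5000)."""
        fit = toy_1d_joint_fit(alpha=0.8, h0=0.0)
        recs = _toy_records()
        hist = history_in_state1(make_baseline(), recs, 3.0)
        draws = sample_posterior_random_effects(fit, hist, n_draws=5000, seed=6)
        assert draws.ess == pytest.approx(5000, rel=1e-6)
        from isletprog.longitudinal import posterior_random_effects

        post = posterior_random_effects(fit.longitudinal, recs)
        res = stats.kstest(draws.draws[:, 0], "norm", args=(post.mean[0], np.sqrt(post.cov[0, 0])))
        assert res.pvalue > 0.01

    def test_zero_records_zero_hazard_prior_draws(self):
        fit = toy_1d_joint_fit(alpha=0.8, h0=0.0, tau2=0.25)
        hist = history_in_state1(make_baseline(), [], 2.0)
        draws = sample_posterior_random_effects(fit, hist, n_draws=5000, seed=7)
        res = stats.kstest(draws.draws[:, 0], "norm", args=(0.0, 0.5))
        assert res.pvalue > 0.01

    def test_survival_weighting_shifts_posterior_down(self):
        """Surviving a high positive-association hazard implies lower latent
        values: the weighted mean drops below the proposal mean."""
        fit = toy_1d_joint_fit(alpha=2.0, h0=0.8)
        hist = history_in_state1(make_baseline(), _toy_records(times=(0.0, 1.0)), 6.0)
        draws = sample_posterior_random_effects(fit, hist, n_draws=4000, seed=8)
        weighted_mean = float(draws.weights @ draws.draws[:, 0])
        assert weighted_mean < draws.proposal.mean[0] - 0.02


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

class TestPredictTrajectory:
    def test_zero_records_gives_population_curve_with_prior_band(self):
        fit = toy_1d_joint_fit(alpha=0.0, h0=0.0, tau2=0.25)
        hist = history_in_state1(make_baseline(), [], 1.0)
        out = predict_trajectory(fit, hist, horizon=4.0, n_draws=3000, seed=9)["hba1c"]
        pop = 5.0 + 0.1 * out["times"]
        np.testing.assert_allclose(out["mean"], pop, atol=0.05)
        halfwidth = (out["upper"] - out["lower"]) / 2
        np.testing.assert_allclose(halfwidth, 1.96 * 0.5, atol=0.07)
        assert np.all(out["lower"] <= out["mean"]) and np.all(out["mean"] <= out["upper"])

    def test_dense_noiseless_history_collapses_band(self):
        fit = toy_1d_joint_fit(alpha=0.0, h0=0.0, tau2=0.25, sigma=0.01)
        recs = [LongitudinalRecord("hba1c", t, 5.0 + 0.1 * t + 0.3) for t in np.linspace(0, 3, 25)]
        hist = history_in_state1(make_baseline(), recs, 3.0)
        out = predict_trajectory(fit, hist, horizon=2.0, n_draws=1000, seed=10)["hba1c"]
        assert np.all(out["upper"] - out["lower"] < 0.02)
        np.testing.assert_allclose(out["mean"], 5.0 + 0.1 * out["times"] + 0.3, atol=0.01)

    def test_nonpositive_horizon_rejected(self):
        fit = toy_1d_joint_fit()
        hist = history_in_state1(make_baseline(), [], 1.0)
        with pytest.raises(ValueError, match="horizon"):
            predict_trajectory(fit, hist, horizon=0.0)


class TestPredictOccupancy:
    def test_indicator_at_landmark_and_constant_when_hazards_zero(self):
        fit = toy_1d_joint_fit(alpha=0.5, h0=0.0)
        hist = history_in_state1(make_baseline(), _toy_records(), 2.0)
        pred = predict_occupancy(fit, hist, grid=[2.0, 4.0, 9.0], n_draws=100, seed=11)
        np.testing.assert_allclose(pred.occupancy[0], [1, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(
            pred.occupancy, np.tile(pred.occupancy[0], (len(pred.times), 1)), atol=1e-12
        )

    def test_alpha_zero_reduces_to_transition_matrix(self):
        """No association and no fixed covariates: prediction equals the pure
        multistate product integral, with no draw dependence."""
        lfit = toy_1d_longitudinal_fit()
        tms = {
            (1, 2): TransitionModel((1, 2), (), np.zeros(0), PiecewiseConstantHazard((), (0.25,))),
            (2, 4): TransitionModel((2, 4), (), np.zeros(0), PiecewiseConstantHazard((), (0.15,))),
            (1, 4): TransitionModel((1, 4), (), np.zeros(0), PiecewiseConstantHazard((), (0.05,))),
        }
        fit = ip.JointModelFit(longitudinal=lfit, transitions=tms)
        hist = history_in_state1(make_baseline(), [], 1.5)
        grid = [1.5, 3.0, 6.0, 11.0]
        pred = predict_occupancy(fit, hist, grid, n_draws=25, seed=12)
        for g, u in enumerate(grid):
            P = transition_probability_matrix(tms, CovariatePath(make_baseline()), 1.5, u, step=1 / 120)
            np.testing.assert_allclose(pred.occupancy[g], P[0], atol=1e-9)
            assert np.all(pred.mc_se[g] < 1e-9)

    def test_rows_normalized_absorption_monotone_all_seeds(self):
        cfg = ip.default_config(n_subjects=0)
        fit = ip.truth_joint_fit(cfg)
        recs = _toy_records(beta=(5.2, 0.03))
        hist = history_in_state1(make_baseline(), recs, 2.0)
        grid = np.linspace(2.0, 10.0, 9)
        for seed in (1, 2, 3):
            pred = predict_occupancy(fit, hist, grid, n_draws=120, seed=seed)
            np.testing.assert_allclose(pred.occupancy.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(np.diff(pred.occupancy[:, 3]) >= -1e-9)

    def test_prediction_from_absorbing_state_rejected(self):
        fit = toy_1d_joint_fit()
        hist = SubjectHistory(
            baseline=make_baseline(), records=[], state_path=[StateRecord(1, 0.0, 2.0, 4)]
        )
        with pytest.raises(ValueError, match="absorbing"):
            predict_occupancy(fit, hist, grid=[2.0, 3.0])

    def test_self_consistency_against_forward_simulation(self):
        """Degenerate-random-effects truth: predicted occupancy equals the
        frequency of forward-simulated futures (3 MC SD)."""
        cfg = ip.default_config(n_subjects=0)
        cfg.sigma_b = np.zeros_like(cfg.sigma_b)
        fit = ip.truth_joint_fit(cfg)
        baseline = make_baseline(age=4.0)
        hist = history_in_state1(baseline, [], 1.0)
        grid = [3.0, 6.0]
        pred = predict_occupancy(fit, hist, grid, n_draws=30, seed=13)
        rng = np.random.default_rng(14)
        traj = simulate_trajectories(baseline, cfg, rng)
        n_fut = 1000
        counts = np.zeros((len(grid), 4))
        for _ in range(n_fut):
            recs = simulate_transitions(
                baseline, traj, cfg, rng, start_state=1, start_time=1.0, censor_time=11.0
            )
            subj = Subject(id="F", baseline=baseline, path=recs)
            for g, u in enumerate(grid):
                counts[g, subj.state_at(u) - 1] += 1
        freq = counts / n_fut
        for g in range(len(grid)):
            for r in range(4):
                p = pred.occupancy[g, r]
                tol = 3 * np.sqrt(max(p * (1 - p), 1e-4) / n_fut)
                assert abs(freq[g, r] - p) < tol + 0.005


class TestUpdatePrediction:
    def test_empty_update_leaves_prediction_unchanged(self):
        fit = toy_1d_joint_fit(alpha=0.6, h0=0.1)
        hist = history_in_state1(make_baseline(), _toy_records(), 3.0)
        grid = [3.0, 5.0, 8.0]
        base = predict_occupancy(fit, hist, grid, n_draws=300, seed=15)
        upd = update_prediction(fit, hist, [], [], grid, n_draws=300, seed=15)
        np.testing.assert_allclose(upd.occupancy, base.occupancy, atol=1e-12)

    def test_progression_to_ia2a_state_raises_diabetes_risk(self):
        """Updating with an observed transition into the IA-2A-positive state
        gives a uniformly higher predicted diabetes probability than updating
        with continued single-GADA status over the same window."""
        cfg = ip.default_config(n_subjects=0)
        fit = ip.truth_joint_fit(cfg)
        baseline = make_baseline(age=4.0)
        recs = _toy_records(beta=(5.2, 0.03))
        old = history_in_state1(baseline, recs, 3.0)
        grid = np.linspace(5.5, 10.0, 6)
        progressed = [StateRecord(1, 3.0, 3.5, 3), StateRecord(3, 3.5, 5.0, None)]
        stayed = [StateRecord(1, 3.0, 5.0, None)]
        pred_prog = update_prediction(fit, old, [], progressed, grid, n_draws=150, seed=16)
        pred_stay = update_prediction(fit, old, [], stayed, grid, n_draws=150, seed=16)
        assert np.all(pred_prog.occupancy[:, 3] > pred_stay.occupancy[:, 3])
        # and at long horizons it also exceeds the earlier landmark's forecast
        pred_old = predict_occupancy(fit, old, grid, n_draws=150, seed=16)
        assert pred_prog.occupancy[-1, 3] > pred_old.occupancy[-1, 3]

    def test_contradictory_state_info_rejected(self):
        fit = toy_1d_joint_fit()
        hist = history_in_state1(make_baseline(), [], 2.0)
        with pytest.raises(ValueError, match="contradicts"):
            update_prediction(fit, hist, [], [StateRecord(2, 2.0, 3.0, None)], [3.0])


# ---------------------------------------------------------------------------
# fit_joint
# ---------------------------------------------------------------------------

def _toy_spec():
    return LongitudinalSpec(
        "hba1c", SplineSpec("piecewise_linear", (), boundary=(0.0, 15.0)),
        log_transformed=False, random_terms=(0,),
    )


def _simulate_toy_cohort(n, alpha, seed, tau=0.5, sigma=0.3, h0=0.08):
    """1-variable random-intercept cohort with a single 1->4 transition."""
    cfg = SimulationConfig(
        n_subjects=0,
        specs=[_toy_spec()],
        beta={"hba1c": np.array([5.0, 0.1])},
        sigma_b=np.array([[tau**2]]),
        sigma={"hba1c": sigma},
        transition_coefs={(1, 4): (("hba1c", alpha),)},
        baseline_hazards={(1, 4): ((), (h0,))},
    )
    rng = np.random.default_rng(seed)
    subs = []
    for i in range(n):
        baseline = make_baseline(age=4.0)
        traj = simulate_trajectories(baseline, cfg, rng)
        path = simulate_transitions(baseline, traj, cfg, rng, censor_time=8.0)
        end = path[-1].exit_time
        times = np.arange(0.0, end + 1e-9, 0.5)
        recs = [
            LongitudinalRecord("hba1c", t, traj.value("hba1c", t)[0] + rng.normal(0, sigma))
            for t in times
        ]
        subs.append(Subject(id=f"T{i}", baseline=baseline, longitudinal=recs, path=path))
    return Cohort(subjects=subs), cfg


class TestFitJoint:
    def test_zero_association_joint_matches_two_stage(self):
        """alpha = 0 decouples the submodels: joint refinement stays at the
        two-stage estimate."""
        cohort, _ = _simulate_toy_cohort(n=80, alpha=0.0, seed=17)
        settings = IntegrationSettings(joint_refine=True, refine_maxiter=25)
        fit = fit_joint(cohort, [_toy_spec()], settings, rosters={(1, 4): ("hba1c",)})
        two_stage = fit.stagewise["transitions"][(1, 4)][0]
        joint_alpha = fit.transitions[(1, 4)].coef[0]
        assert abs(joint_alpha - two_stage) < 0.06
        assert abs(joint_alpha) < 0.5  # truth is zero

    def test_refit_is_deterministic(self):
        cohort, _ = _simulate_toy_cohort(n=30, alpha=0.5, seed=18)
        settings = IntegrationSettings(joint_refine=True, refine_maxiter=5)
        a = fit_joint(cohort, [_toy_spec()], settings, rosters={(1, 4): ("hba1c",)})
        b = fit_joint(cohort, [_toy_spec()], settings, rosters={(1, 4): ("hba1c",)})
        np.testing.assert_array_equal(a.transitions[(1, 4)].coef, b.transitions[(1, 4)].coef)
        assert a.log_likelihood == b.log_likelihood

    def test_joint_less_attenuated_than_locf(self):
        """Measurement noise attenuates the naive last-observation-carried-
        forward hazard fit; the joint estimate stays closer to truth in most
        replicates."""
        from isletprog.multistate import fit_multistate

        alpha_true = 0.8
        wins = 0
        n_rep = 5
        for rep in range(n_rep):
            cohort, _ = _simulate_toy_cohort(n=120, alpha=alpha_true, seed=30 + rep, sigma=0.45)
            # LOCF comparator
            locf_paths = {}
            for s in cohort:
                ts = np.array([r.time for r in s.longitudinal])
                vs = np.array([r.value for r in s.longitudinal])

                def locf(v, t, ts=ts, vs=vs):
                    idx = np.clip(np.searchsorted(ts, t, side="right") - 1, 0, len(ts) - 1)
                    return vs[idx]

                locf_paths[s.id] = CovariatePath(s.baseline, trajectory=locf)
            locf_models, _ = fit_multistate(
                cohort, locf_paths, lam=0.0, rosters={(1, 4): ("hba1c",)}, cuts={(1, 4): ()}
            )
            locf_alpha = locf_models[(1, 4)].coef[0]
            settings = IntegrationSettings(joint_refine=True, refine_maxiter=20)
            jfit = fit_joint(cohort, [_toy_spec()], settings, rosters={(1, 4): ("hba1c",)})
            joint_alpha = jfit.transitions[(1, 4)].coef[0]
            wins += abs(joint_alpha - alpha_true) < abs(locf_alpha - alpha_true)
        assert wins >= 0.6 * n_rep
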