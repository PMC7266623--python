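"""Tests of the Kalman and Delta learning rules, including a grid-Bayes oracle."""

import numpy as np
import pytest

from restless_bandits.learning import (
    DeltaState,
    KalmanState,
    LearnerParams,
    delta_update,
    kalman_drift,
    kalman_gain,
    kalman_observe,
    run_learner,
)


def grid_bayes_posterior(mu0, var0, reward, obs_var, half_width=10.0, n=40_001):
    """Brute-force conjugate update: discretized Gaussian prior x likelihood."""
    sd = max(np.sqrt(var0), np.sqrt(obs_var))
    lo = min(mu0, reward) - half_width * sd
    hi = max(mu0, reward) + half_width * sd
    grid = np.linspace(lo, hi, n)
    log_post = (
        -0.5 * (grid - mu0) ** 2 / var0 - 0.5 * (reward - grid) ** 2 / obs_var
    )
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    mean = float(np.sum(w * grid))
    var = float(np.sum(w * (grid - mean) ** 2))
    return mean, var


class TestKalmanGain:
    @pytest.mark.parametrize(
        "prior_var,obs_var,expected", [(16, 16, 0.5), (48, 16, 0.75)]
    )
    def test_gain_arithmetic(self, prior_var, obs_var, expected):
        assert kalman_gain(prior_var, obs_var) == pytest.approx(expected)

    def test_gain_vanishes_with_prior_certainty(self):
        assert kalman_gain(1e-12, 16.0) < 1e-12

    def test_gain_strictly_within_unit_interval(self, rng):
        for _ in range(200):
            pv, ov = rng.uniform(1e-6, 1e3, size=2)
            assert 0.0 < kalman_gain(pv, ov) < 1.0

    @pytest.mark.parametrize("pv,ov", [(0, 16), (-1, 16), (16, 0)])
    def test_nonpositive_variances_rejected(self, pv, ov):
        with pytest.raises(ValueError):
            kalman_gain(pv, ov)


class TestKalmanObserve:
    def setup_method(self):
        self.params = LearnerParams()
        self.state = KalmanState(
            prior_mean=np.full(4, 50.0), prior_var=np.full(4, 16.0)
        )

    def test_conjugate_update_worked_example(self):
        new, rec = kalman_observe(self.state, 0, 66.0, self.params)
        assert rec.kalman_gain == pytest.approx(0.5)
        assert rec.prediction_error == pytest.approx(16.0)
        assert rec.posterior_mean == pytest.approx(58.0)
        assert rec.posterior_var == pytest.approx(8.0)
        assert new.prior_mean[0] == pytest.approx(58.0)

    def test_zero_prediction_error_keeps_mean_shrinks_variance(self):
        new, rec = kalman_observe(self.state, 1, 50.0, self.params)
        assert rec.prediction_error == 0.0
        assert new.prior_mean[1] == pytest.approx(50.0)
        assert new.prior_var[1] < self.state.prior_var[1]

    def test_unchosen_bandits_keep_their_priors(self):
        new, _ = kalman_observe(self.state, 0, 80.0, self.params)
        assert np.array_equal(new.prior_mean[1:], self.state.prior_mean[1:])
        assert np.array_equal(new.prior_var[1:], self.state.prior_var[1:])

    def test_posterior_variance_always_below_prior(self, rng):
        for _ in range(50):
            state = KalmanState(
                prior_mean=rng.normal(50, 20, 4),
                prior_var=rng.uniform(0.5, 400, 4),
            )
            c = int(rng.integers(4))
            _, rec = kalman_observe(state, c, float(rng.normal(50, 20)), self.params)
            assert rec.posterior_var < state.prior_var[c]

    def test_nonfinite_reward_rejected(self):
        with pytest.raises(ValueError):
            kalman_observe(self.state, 0, float("nan"), self.params)

    def test_matches_grid_bayes_oracle_on_randomized_instances(self, rng):
        """Acceptance-grade oracle: 100 random instances, mean/sd within 1e-3."""
        for _ in range(100):
            mu0 = float(rng.uniform(0, 100))
            var0 = float(rng.uniform(1.0, 300.0))
            obs_var = float(rng.uniform(1.0, 100.0))
            reward = float(rng.uniform(0, 100))
            params = LearnerParams(est_obs_var=obs_var)
            state = KalmanState(
                prior_mean=np.array([mu0, 50, 50, 50]),
                prior_var=np.array([var0, 16, 16, 16]),
            )
            _, rec = kalman_observe(state, 0, reward, params)
            mean, var = grid_bayes_posterior(mu0, var0, reward, obs_var)
            assert rec.posterior_mean == pytest.approx(mean, abs=1e-3)
            assert np.sqrt(rec.posterior_var) == pytest.approx(
                np.sqrt(var), abs=1e-3
            )


class TestKalmanDrift:
    def test_decay_center_is_fixed_point_of_mean(self):
        params = LearnerParams()
        state = KalmanState(prior_mean=np.full(4, 50.0), prior_var=np.full(4, 9.0))
        new = kalman_drift(state, params)
        assert np.allclose(new.prior_mean, 50.0)

    def test_variance_inflation_from_zero(self):
        params = LearnerParams()
        state = KalmanState(prior_mean=np.full(4, 50.0), prior_var=np.full(4, 1e-15))
        new = kalman_drift(state, params)
        assert np.allclose(new.prior_var, 7.84, atol=1e-10)

    def test_iterated_drift_converges_to_stationary_variance(self):
        params = LearnerParams()
        target = params.est_diff_var / (1 - params.est_lambda**2)
        state = KalmanState(prior_mean=np.full(4, 50.0), prior_var=np.full(4, 1.0))
        for _ in range(2000):
            state = kalman_drift(state, params)
        assert np.allclose(state.prior_var, target, rtol=1e-6)

    def test_unchosen_variance_grows_toward_stationary_from_below(self):
        params = LearnerParams()
        target = params.est_diff_var / (1 - params.est_lambda**2)
        var = 1.0
        for _ in range(100):
            state = KalmanState(prior_mean=np.full(4, 50.0), prior_var=np.full(4, var))
            new_var = kalman_drift(state, params).prior_var[0]
            assert var < new_var < target
            var = new_var


class TestDeltaRule:
    @pytest.mark.parametrize(
        "alpha,reward,expected", [(1.0, 70.0, 70.0), (0.0, 70.0, 50.0), (0.5, 70.0, 60.0)]
    )
    def test_update_arithmetic(self, alpha, reward, expected):
        state = DeltaState.initial(alpha)
        new = delta_update(state, 0, reward)
        assert new.value[0] == pytest.approx(expected)
        assert np.array_equal(new.value[1:], state.value[1:])

    def test_learning_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            DeltaState.initial(1.5)

    def test_kalman_reduces_to_delta_at_constant_gain(self):
        """With lambda_hat=1 and variances at the observed-bandit fixed point,
        repeated observation of one bandit gives a constant gain, so the
        Kalman mean path equals Delta-rule updates with that alpha."""
        params = LearnerParams(
            est_lambda=1.0, est_obs_var=16.0, est_diff_var=8.0,
            init_mean=50.0, init_sd=4.0,
        )  # prior var 16 -> kappa 0.5 -> posterior 8 -> drift restores 16
        kstate = KalmanState.initial(params)
        dstate = DeltaState.initial(0.5)
        rewards = [61.0, 44.0, 58.0, 50.0, 72.0]
        for r in rewards:
            kstate, rec = kalman_observe(kstate, 0, r, params)
            assert rec.kalman_gain == pytest.approx(0.5)
            kstate = kalman_drift(kstate, params)
            dstate = delta_update(dstate, 0, r)
            assert kstate.prior_mean[0] == pytest.approx(dstate.value[0])


class TestRunLearner:
    def test_empty_history_is_initial_prior(self):
        traj = run_learner(np.array([], dtype=int), np.array([]))
        assert traj.n_trials == 0

    def test_single_trial_starts_at_initial_prior(self):
        params = LearnerParams()
        traj = run_learner(np.array([2]), np.array([60.0]), params=params)
        assert np.allclose(traj.mu_pre[0], params.init_mean)
        assert np.allclose(traj.sigma_pre[0], params.init_sd)

    def test_trajectory_matches_manual_composition(self, rng):
        """Full-session trajectory equals step-by-step observe/drift composition."""
        params = LearnerParams()
        n = 300
        choices = rng.integers(0, 4, size=n)
        rewards = rng.uniform(0, 100, size=n)
        traj = run_learner(choices, rewards, params=params)

        state = KalmanState.initial(params)
        for t in range(n):
            assert np.allclose(traj.mu_pre[t], state.prior_mean)
            assert np.allclose(traj.sigma_pre[t], np.sqrt(state.prior_var))
            state, _ = kalman_observe(state, choices[t], rewards[t], params)
            state = kalman_drift(state, params)

    def test_missed_trials_drift_without_update(self):
        params = LearnerParams()
        choices = np.array([0, 0, 0])
        rewards = np.array([80.0, np.nan, 80.0])
        responded = np.array([True, False, True])
        traj = run_learner(choices, rewards, responded, params)
        assert traj.records[1] is None
        # trial 2 prior mean is trial 1 posterior decayed twice, no new reward
        state = KalmanState.initial(params)
        state, _ = kalman_observe(state, 0, 80.0, params)
        state = kalman_drift(state, params)
        state = kalman_drift(state, params)
        assert np.allclose(traj.mu_pre[2], state.prior_mean)

    def test_missing_reward_on_responded_trial_rejected(self):
        with pytest.raises(ValueError):
            run_learner(np.array([0]), np.array([np.nan]))

    def test_chosen_variance_decreases_when_above_fixed_point(self):
        params = LearnerParams()
        traj = run_learner(
            np.zeros(50, dtype=int), np.full(50, 50.0), params=params
        )
        diffs = np.diff(traj.sigma_pre[:, 0])
        assert np.all(diffs <= 0)
        assert np.all(diffs[:10] < 0)  # strict until numerically converged
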