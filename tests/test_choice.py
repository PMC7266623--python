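"""Tests of the four softmax choice rules and the model registry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restless_bandits.choice import (
    MODEL_REGISTRY,
    ChoiceParams,
    choice_prob_sm,
    choice_prob_sme,
    choice_prob_smep,
    choice_prob_smerp,
    choice_probabilities,
    list_models,
    log_likelihood,
)
from restless_bandits._vectorized import loglik_batch, sequence_features

finite_floats = st.floats(
    min_value=-100, max_value=200, allow_nan=False, allow_infinity=False
)
means_arrays = st.lists(finite_floats, min_size=4, max_size=4).map(np.array)
sds_arrays = st.lists(
    st.floats(min_value=0.5, max_value=30), min_size=4, max_size=4
).map(np.array)


class TestSoftmaxRule:
    def test_equal_means_uniform(self):
        assert np.allclose(choice_prob_sm(np.full(4, 50.0), 2.0), 0.25)

    def test_zero_beta_uniform(self):
        assert np.allclose(choice_prob_sm(np.array([90.0, 10, 40, 60]), 0.0), 0.25)

    def test_worked_example(self):
        p = choice_prob_sm(np.array([60.0, 50, 50, 50]), 0.1)
        assert p[0] == pytest.approx(0.4753, abs=5e-4)

    def test_large_values_stable(self):
        p = choice_prob_sm(np.array([1e4, 0.0, 0.0, 0.0]), 10.0)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)


class TestExplorationBonusRule:
    def test_phi_zero_reduces_to_softmax(self):
        means, sds = np.array([60.0, 50, 40, 55]), np.array([3.0, 9, 5, 7])
        assert np.array_equal(
            choice_prob_sme(means, sds, 0.2, 0.0), choice_prob_sm(means, 0.2)
        )

    def test_positive_phi_prefers_uncertain_bandit(self):
        p = choice_prob_sme(np.full(4, 50.0), np.array([2.0, 8, 4, 6]), 0.3, 1.5)
        assert np.argmax(p) == 1

    def test_negative_phi_prefers_certain_bandit(self):
        p = choice_prob_sme(np.full(4, 50.0), np.array([2.0, 8, 4, 6]), 0.3, -1.5)
        assert np.argmax(p) == 0


class TestPerseverationRule:
    def test_rho_zero_reduces_to_exploration_rule(self):
        means, sds = np.array([60.0, 50, 40, 55]), np.array([3.0, 9, 5, 7])
        assert np.array_equal(
            choice_prob_smep(means, sds, 0.2, 1.0, 0.0, previous_choice=2),
            choice_prob_sme(means, sds, 0.2, 1.0),
        )

    def test_worked_example_from_fitted_parameters(self):
        p = choice_prob_smep(
            np.full(4, 50.0), np.full(4, 5.0), 0.29, 0.0, 4.11, previous_choice=0
        )
        expected = np.exp(0.29 * 4.11) / (np.exp(0.29 * 4.11) + 3)
        assert p[0] == pytest.approx(expected)
        assert p[0] == pytest.approx(0.524, abs=1e-3)

    def test_huge_rho_locks_previous_choice(self):
        p = choice_prob_smep(
            np.full(4, 50.0), np.full(4, 5.0), 0.5, 0.0, 1e4, previous_choice=3
        )
        assert p[3] == pytest.approx(1.0)

    def test_first_trial_has_no_perseveration(self):
        p = choice_prob_smep(
            np.full(4, 50.0), np.full(4, 5.0), 0.29, 0.0, 4.11, previous_choice=None
        )
        assert np.allclose(p, 0.25)


class TestTotalUncertaintyRule:
    def test_gamma_zero_reduces_to_perseveration_rule(self):
        means, sds = np.array([60.0, 50, 40, 55]), np.array([3.0, 9, 5, 7])
        assert np.allclose(
            choice_prob_smerp(means, sds, 0.2, 1.0, 2.0, 0.0, previous_choice=1),
            choice_prob_smep(means, sds, 0.2, 1.0, 2.0, previous_choice=1),
        )

    def test_infinite_total_uncertainty_removes_gamma_term(self):
        means = np.array([60.0, 50, 40, 55])
        p_big = choice_prob_smerp(
            means, np.full(4, 1e9), 0.2, 0.0, 0.0, 5.0, previous_choice=None
        )
        p_ref = choice_prob_smep(
            means, np.full(4, 1e9), 0.2, 0.0, 0.0, previous_choice=None
        )
        assert np.allclose(p_big, p_ref, atol=1e-9)

    def test_matches_direct_evaluation(self, rng):
        """Randomized instances against a from-scratch evaluation of rule 4."""
        for _ in range(50):
            means = rng.uniform(20, 80, 4)
            sds = rng.uniform(1, 20, 4)
            beta, phi, rho, gamma = rng.uniform(0.05, 0.5), *rng.normal(0, 2, 3)
            prev = int(rng.integers(4))
            value = means + phi * sds + gamma * means / sds.sum()
            value[prev] += rho
            expected = np.exp(beta * value) / np.exp(beta * value).sum()
            got = choice_prob_smerp(
                means, sds, beta, phi, rho, gamma, previous_choice=prev
            )
            assert np.allclose(got, expected, atol=1e-12)


class TestRuleProperties:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(means=means_arrays, sds=sds_arrays,
           beta=st.floats(0, 2), phi=st.floats(-3, 3), rho=st.floats(-5, 5),
           gamma=st.floats(-3, 3), prev=st.integers(0, 3))
    def test_normalization_and_nonnegativity(self, means, sds, beta, phi, rho,
                                             gamma, prev):
        p = choice_prob_smerp(means, sds, beta, phi, rho, gamma, previous_choice=prev)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_translation_invariance_of_augmented_values(self):
        means, sds = np.array([60.0, 50, 40, 55]), np.array([3.0, 9, 5, 7])
        p1 = choice_prob_sme(means, sds, 0.2, 1.0)
        p2 = choice_prob_sme(means + 500.0, sds, 0.2, 1.0)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_label_equivariance(self, rng):
        means, sds = rng.uniform(20, 80, 4), rng.uniform(1, 20, 4)
        perm = np.array([2, 0, 3, 1])
        p = choice_prob_sme(means, sds, 0.2, 1.0)
        p_perm = choice_prob_sme(means[perm], sds[perm], 0.2, 1.0)
        assert np.allclose(p[perm], p_perm)

    def test_dispatcher_matches_direct_calls(self):
        means, sds = np.array([60.0, 50, 40, 55]), np.array([3.0, 9, 5, 7])
        cp = ChoiceParams(beta=0.2, phi=1.0, rho=2.0, gamma=0.5, previous_choice=1)
        assert np.array_equal(
            choice_probabilities("smerp", means, sds, cp),
            choice_prob_smerp(means, sds, 0.2, 1.0, 2.0, 0.5, previous_choice=1),
        )


class TestModelRegistry:
    def test_exactly_eight_models_two_learners_by_four_rules(self):
        names = list_models()
        assert len(names) == 8
        assert {MODEL_REGISTRY[n].learner for n in names} == {"delta", "bayes"}
        assert {MODEL_REGISTRY[n].rule for n in names} == {
            "sm", "sme", "smep", "smerp"
        }

    def test_delta_models_add_learning_rate(self):
        assert MODEL_REGISTRY["delta-smep"].free_params == (
            "alpha", "beta", "phi", "rho",
        )
        assert MODEL_REGISTRY["bayes-sm"].free_params == ("beta",)


class TestLogLikelihood:
    def test_zero_beta_gives_uniform_likelihood(self, rng):
        n = 40
        choices = rng.integers(0, 4, n)
        rewards = rng.uniform(0, 100, n)
        ll = log_likelihood(choices, rewards, model="bayes-sm", params={"beta": 0.0})
        assert ll == pytest.approx(n * np.log(0.25))

    def test_single_uniform_trial(self):
        ll = log_likelihood(
            np.array([1]), np.array([55.0]), model="bayes-sm", params={"beta": 0.0}
        )
        assert ll == pytest.approx(np.log(0.25))

    def test_missed_trials_excluded(self, rng):
        choices = np.array([0, 1, 2, 3])
        rewards = np.array([50.0, np.nan, 50.0, 50.0])
        responded = np.array([True, False, True, True])
        ll = log_likelihood(
            choices, rewards, responded, model="bayes-sm", params={"beta": 0.0}
        )
        assert ll == pytest.approx(3 * np.log(0.25))

    def test_composition_matches_per_trial_oracle(self, rng):
        """10-trial sequence: total equals an independently composed sum."""
        from restless_bandits.learning import (
            KalmanState,
            LearnerParams,
            kalman_drift,
            kalman_observe,
        )

        params = {"beta": 0.3, "phi": 1.2, "rho": 3.0}
        lp = LearnerParams()
        choices = np.array([0, 1, 1, 2, 3, 1, 0, 0, 2, 1])
        rewards = np.array([62.0, 48, 55, 71, 30, 52, 64, 66, 40, 57])

        state = KalmanState.initial(lp)
        prev = None
        expected = 0.0
        for t in range(10):
            value = state.prior_mean + params["phi"] * np.sqrt(state.prior_var)
            if prev is not None:
                value = value.copy()
                value[prev] += params["rho"]
            z = params["beta"] * value
            p = np.exp(z - z.max())
            p /= p.sum()
            expected += np.log(p[choices[t]])
            state, _ = kalman_observe(state, choices[t], rewards[t], lp)
            state = kalman_drift(state, lp)
            prev = choices[t]

        got = log_likelihood(choices, rewards, model="bayes-smep", params=params)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_missing_required_parameter_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            log_likelihood(
                np.array([0]), np.array([50.0]), model="bayes-sme",
                params={"beta": 0.2},
            )

    @pytest.mark.parametrize("model", list_models())
    def test_vectorized_likelihood_matches_scalar_path(self, model, rng):
        """The batched MCMC likelihood agrees with the per-trial scalar path
        for every one of the eight models."""
        n = 60
        choices = rng.integers(0, 4, n)
        rewards = rng.uniform(0, 100, n)
        responded = rng.random(n) > 0.05
        rewards[~responded] = np.nan
        params = {
            "alpha": 0.4, "beta": 0.25, "phi": 1.1, "rho": 2.5, "gamma": -0.8,
        }
        free = MODEL_REGISTRY[model].free_params
        use = {k: v for k, v in params.items() if k in free}
        scalar = log_likelihood(choices, rewards, responded, model=model, params=use)
        feat = sequence_features(choices, rewards, responded)
        batched = loglik_batch(
            feat, model,
            beta=use["beta"], phi=use.get("phi"), rho=use.get("rho"),
            gamma=use.get("gamma"), alpha=use.get("alpha"),
        )[0]
        assert batched == pytest.approx(scalar, abs=1e-9)
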