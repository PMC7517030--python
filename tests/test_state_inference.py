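import math

import numpy as np
import pytest

from planinf.inference import (
    filter_forward,
    posterior_given_policy,
    predict,
    predict_actions,
    update_dirichlet,
)
from planinf.model import (
    AgentModel,
    CategoricalDist,
    HabitPrior,
    LikelihoodModel,
    Policy,
    PreferenceModel,
    TransitionModel,
    default_precision_prior,
)
from planinf.sampling import random_agent_model, random_observations

from oracles import enum_log_evidence, enum_predictions, enum_smoothed


class TestPosteriorGivenPolicy:
    def test_identity_likelihood_single_observation(self, identity_model):
        post = posterior_given_policy(identity_model, identity_model.policies[0], [0])
        np.testing.assert_allclose(post.smoothed[0], [1.0, 0.0], atol=1e-12)
        assert post.log_evidence == pytest.approx(math.log(0.5), abs=1e-12)

    def test_uninformative_likelihood_leaves_prior(self, two_state_model):
        # identical columns: observations carry no information about states
        two_state_model.likelihood = LikelihoodModel(
            np.array([[0.7, 0.7], [0.3, 0.3]])
        )
        post = posterior_given_policy(
            two_state_model, two_state_model.policies[0], [0, 1]
        )
        for t in range(2):
            np.testing.assert_allclose(post.smoothed[t], [0.5, 0.5], atol=1e-12)

    def test_bayes_rule_oracle(self, two_state_model):
        post = posterior_given_policy(two_state_model, two_state_model.policies[0], [0])
        np.testing.assert_allclose(post.smoothed[0], [9 / 11, 2 / 11], atol=1e-4)
        assert post.log_evidence == pytest.approx(math.log(0.55), abs=1e-12)

    def test_matches_trajectory_enumeration(self):
        """F(pi) and the smoothed marginals agree with brute-force summation."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            model = random_agent_model(rng, horizon=3)
            policy = model.policies[0]
            obs = random_observations(rng, model, length=policy.horizon + 1)
            post = posterior_given_policy(model, policy, obs)
            assert post.log_evidence == pytest.approx(
                enum_log_evidence(model, policy, obs), abs=1e-10
            )
            np.testing.assert_allclose(
                post.smoothed, enum_smoothed(model, policy, obs), atol=1e-10
            )

    def test_posterior_normalized_every_timestep(self):
        rng = np.random.default_rng(42)
        model = random_agent_model(rng, horizon=3)
        obs = random_observations(rng, model, length=4)
        post = posterior_given_policy(model, model.policies[0], obs)
        np.testing.assert_allclose(post.smoothed.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(post.filtered.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_observation_raises(self, two_state_model):
        with pytest.raises(ValueError):
            posterior_given_policy(two_state_model, two_state_model.policies[0], [5])

    def test_empty_observations_raise(self, two_state_model):
        with pytest.raises(ValueError):
            posterior_given_policy(two_state_model, two_state_model.policies[0], [])


class TestPredict:
    def test_identity_transitions_hold_belief(self, identity_model):
        pred = predict_actions(identity_model, [0, 0, 0], np.array([0.3, 0.7]))
        for k in range(3):
            np.testing.assert_allclose(pred.states[k], [0.3, 0.7], atol=1e-12)

    def test_deterministic_cycle(self):
        B = np.zeros((1, 3, 3))
        for s in range(3):
            B[0, (s + 1) % 3, s] = 1.0
        model = AgentModel(
            likelihood=LikelihoodModel(np.eye(3)),
            transitions=TransitionModel(B),
            preferences=PreferenceModel(np.zeros(3)),
            initial_states=CategoricalDist(np.array([1.0, 0.0, 0.0])),
            habits=HabitPrior(np.zeros((1, 1))),
            precision_prior=default_precision_prior(),
            policies=[Policy((0, 0), id=0)],
        )
        pred = predict(model, model.policies[0], model.initial_states)
        np.testing.assert_allclose(pred.states[0], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(pred.states[1], [0, 0, 1], atol=1e-12)

    def test_outcome_prediction_is_likelihood_applied_to_states(self):
        rng = np.random.default_rng(5)
        model = random_agent_model(rng, n_states=3, horizon=3)
        belief = rng.dirichlet(np.ones(3))
        pred = predict_actions(model, model.policies[0].actions, belief)
        np.testing.assert_allclose(
            pred.outcomes, pred.states @ model.likelihood.matrix.T, atol=1e-12
        )

    def test_matches_enumeration_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            model = random_agent_model(rng, n_states=3, horizon=3)
            belief = rng.dirichlet(np.ones(3))
            actions = list(model.policies[0].actions)
            pred = predict_actions(model, actions, belief)
            np.testing.assert_allclose(
                pred.states, enum_predictions(model, actions, belief), atol=1e-10
            )

    def test_horizon_zero_is_empty(self, two_state_model):
        pred = predict_actions(two_state_model, [], np.array([0.5, 0.5]))
        assert pred.horizon == 0


class TestUpdateDirichlet:
    def test_point_belief_increments_single_count(self):
        lik = LikelihoodModel.from_counts(np.ones((2, 2)))
        new = update_dirichlet(lik, observation=0, state_belief=np.array([1.0, 0.0]))
        assert new.counts[0, 0] == pytest.approx(2.0)
        assert new.counts.sum() == pytest.approx(lik.counts.sum() + 1.0)

    def test_fully_frozen_mask_blocks_all_change(self):
        lik = LikelihoodModel.from_counts(
            np.ones((2, 2)), frozen_mask=np.ones((2, 2), dtype=bool)
        )
        new = update_dirichlet(lik, 1, np.array([0.4, 0.6]), rate=3.0)
        np.testing.assert_array_equal(new.counts, lik.counts)
        np.testing.assert_array_equal(new.matrix, lik.matrix)

    def test_missing_counts_is_an_error(self):
        lik = LikelihoodModel(np.eye(2))
        with pytest.raises(ValueError):
            update_dirichlet(lik, 0, np.array([1.0, 0.0]))

    def test_learning_converges_toward_truth(self):
        """KL(true column || learned column) shrinks over 500 observations."""
        rng = np.random.default_rng(0)
        true_col = np.array([0.7, 0.2, 0.1])
        lik = LikelihoodModel.from_counts(np.ones((3, 1)))

        def kl_to_truth(l):
            col = l.matrix[:, 0]
            return float((true_col * np.log(true_col / col)).sum())

        kl_start = kl_to_truth(lik)
        checkpoints = []
        for i in range(500):
            o = rng.choice(3, p=true_col)
            lik = update_dirichlet(lik, int(o), np.array([1.0]))
            if (i + 1) % 100 == 0:
                checkpoints.append(kl_to_truth(lik))
        assert checkpoints[-1] < kl_start
        assert checkpoints[-1] < 0.01


def test_filter_forward_matches_policy_filtering(two_state_model):
    obs = [0, 1]
    filtered = filter_forward(two_state_model, [1], obs)
    post = posterior_given_policy(two_state_model, two_state_model.policies[1], obs)
    np.testing.assert_allclose(filtered, post.filtered, atol=1e-12)
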