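import numpy as np
import pytest

from planinf.inference import PredictiveBeliefs
from planinf.model import LikelihoodModel, PreferenceModel
from planinf.objectives import (
    MI_METHODS,
    ambiguity,
    dirichlet_kl,
    expected_free_energy,
    kl_value,
    mutual_information,
    parameter_info_gain,
)
from planinf.sampling import random_agent_model

from oracles import beta_kl_quad, kl as kl_oracle, mi_double_sum


def one_step_predictive(qs, A):
    qs = np.asarray(qs, dtype=float)
    return PredictiveBeliefs(states=qs[None, :], outcomes=(A @ qs)[None, :])


WORKHORSE_A = np.array([[0.9, 0.2], [0.1, 0.8]])


class TestMutualInformation:
    def test_uninformative_likelihood_gives_zero(self):
        A = np.array([[0.6, 0.6], [0.4, 0.4]])
        lik = LikelihoodModel(A)
        for method in MI_METHODS:
            pred = one_step_predictive([0.3, 0.7], A)
            assert mutual_information(pred, lik, method) == pytest.approx(0.0, abs=1e-12)

    def test_identity_likelihood_uniform_states(self):
        A = np.eye(2)
        pred = one_step_predictive([0.5, 0.5], A)
        for method in MI_METHODS:
            assert mutual_information(pred, LikelihoodModel(A), method) == pytest.approx(
                np.log(2), abs=1e-12
            )

    def test_workhorse_value_against_double_sum_oracle(self):
        qs = np.array([0.5, 0.5])
        expected = mi_double_sum(WORKHORSE_A, qs)
        assert expected == pytest.approx(0.2754, abs=5e-5)
        pred = one_step_predictive(qs, WORKHORSE_A)
        for method in MI_METHODS:
            got = mutual_information(pred, LikelihoodModel(WORKHORSE_A), method)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_factorizations_agree_on_random_models(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            model = random_agent_model(rng, horizon=2)
            qs = rng.dirichlet(np.ones(model.n_states))
            pred = one_step_predictive(qs, model.likelihood.matrix)
            vals = [
                mutual_information(pred, model.likelihood, m) for m in MI_METHODS
            ]
            assert max(vals) - min(vals) < 1e-10
            assert min(vals) >= 0.0

    def test_unknown_method_raises(self, two_state_model):
        pred = one_step_predictive([0.5, 0.5], WORKHORSE_A)
        with pytest.raises(ValueError):
            mutual_information(pred, two_state_model.likelihood, "bogus")

    def test_multi_step_sums_per_timestep(self):
        qs = np.array([0.5, 0.5])
        one = one_step_predictive(qs, WORKHORSE_A)
        two = PredictiveBeliefs(
            states=np.vstack([qs, qs]), outcomes=np.vstack([WORKHORSE_A @ qs] * 2)
        )
        lik = LikelihoodModel(WORKHORSE_A)
        assert mutual_information(two, lik) == pytest.approx(
            2 * mutual_information(one, lik), abs=1e-12
        )


class TestKLValue:
    def test_matching_distributions_give_zero(self):
        prefs = PreferenceModel(np.log([0.75, 0.25]))
        assert kl_value(np.array([0.75, 0.25]), prefs) == pytest.approx(0.0, abs=1e-12)

    def test_any_mismatch_is_strictly_negative(self):
        prefs = PreferenceModel(np.zeros(2))
        assert kl_value(np.array([0.9, 0.1]), prefs) < 0

    def test_derived_value(self):
        prefs = PreferenceModel(np.zeros(2))  # normalises to [0.5, 0.5]
        got = kl_value(np.array([0.75, 0.25]), prefs)
        assert got == pytest.approx(-0.13081, abs=1e-5)
        assert got == pytest.approx(-kl_oracle([0.75, 0.25], [0.5, 0.5]), abs=1e-12)


class TestAmbiguity:
    def test_deterministic_likelihood_is_unambiguous(self):
        assert ambiguity(LikelihoodModel(np.eye(3)), np.ones(3) / 3) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_uniform_likelihood_gives_log_k(self):
        K = 4
        A = np.full((K, 2), 1.0 / K)
        for qs in ([0.5, 0.5], [0.9, 0.1]):
            assert ambiguity(LikelihoodModel(A), np.array(qs)) == pytest.approx(
                np.log(K), abs=1e-12
            )

    def test_workhorse_value(self):
        got = ambiguity(LikelihoodModel(WORKHORSE_A), np.array([0.5, 0.5]))
        expected = -0.5 * (
            0.9 * np.log(0.9) + 0.1 * np.log(0.1) + 0.2 * np.log(0.2) + 0.8 * np.log(0.8)
        )
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.41274, abs=5e-5)


class TestParameterInfoGain:
    def test_fully_frozen_counts_contribute_nothing(self):
        lik = LikelihoodModel.from_counts(
            np.ones((2, 2)), frozen_mask=np.ones((2, 2), dtype=bool)
        )
        pred = one_step_predictive([0.5, 0.5], lik.matrix)
        assert parameter_info_gain(lik, pred) == 0.0

    def test_known_parameters_have_vanishing_novelty(self):
        lik = LikelihoodModel.from_counts(1e6 * np.ones((2, 2)))
        pred = one_step_predictive([0.5, 0.5], lik.matrix)
        assert parameter_info_gain(lik, pred) < 1e-5

    def test_missing_counts_return_zero(self):
        lik = LikelihoodModel(np.eye(2))
        pred = one_step_predictive([0.5, 0.5], lik.matrix)
        assert parameter_info_gain(lik, pred) == 0.0

    def test_unit_counts_match_beta_quadrature_oracle(self):
        """2x2 unit counts: each update is Beta(2,1) vs Beta(1,1) per column."""
        lik = LikelihoodModel.from_counts(np.ones((2, 2)))
        pred = one_step_predictive([0.5, 0.5], lik.matrix)
        got = parameter_info_gain(lik, pred)
        # every (o, s) update is KL[Beta(2,1) || Beta(1,1)] by symmetry
        expected = beta_kl_quad(2, 1, 1, 1)
        assert got == pytest.approx(expected, abs=1e-7)
        assert got > 0

    def test_closed_form_dirichlet_kl_matches_quadrature(self):
        assert dirichlet_kl([3.0, 1.5], [2.0, 1.5]) == pytest.approx(
            beta_kl_quad(3.0, 1.5, 2.0, 1.5), abs=1e-8
        )

    def test_scaling_counts_never_increases_novelty(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            model = random_agent_model(rng, with_counts=True)
            qs = rng.dirichlet(np.ones(model.n_states))
            pred = one_step_predictive(qs, model.likelihood.matrix)
            base = parameter_info_gain(model.likelihood, pred)
            for c in (2.0, 10.0):
                scaled = LikelihoodModel.from_counts(c * model.likelihood.counts)
                assert parameter_info_gain(scaled, pred) <= base + 1e-12


class TestExpectedFreeEnergy:
    def test_identity_flat_model_cancels_exactly(self, identity_model):
        pred = one_step_predictive([0.5, 0.5], identity_model.likelihood.matrix)
        efe = expected_free_energy(identity_model, pred)
        assert efe.G_total == pytest.approx(0.0, abs=1e-12)
        assert efe.info_gain == pytest.approx(np.log(2), abs=1e-12)
        assert efe.utility == pytest.approx(-np.log(2), abs=1e-12)

    def test_workhorse_value_via_both_decompositions(self, two_state_model):
        pred = one_step_predictive([0.5, 0.5], WORKHORSE_A)
        efe = expected_free_energy(two_state_model, pred)
        assert efe.G_total == pytest.approx(-0.41775, abs=5e-5)
        # G = I + utility
        assert efe.G_total == pytest.approx(efe.info_gain + efe.utility, abs=1e-12)
        # G = V - ambiguity
        v = kl_value(pred.outcomes[0], two_state_model.preferences)
        assert efe.G_total == pytest.approx(v - efe.ambiguity, abs=1e-10)

    def test_internal_identities_on_random_models(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            model = random_agent_model(rng, horizon=2, with_counts=seed % 2 == 0)
            qs = rng.dirichlet(np.ones(model.n_states))
            from planinf.inference import predict_actions

            pred = predict_actions(model, model.policies[0].actions, qs)
            efe = expected_free_energy(model, pred)
            assert efe.info_gain == pytest.approx(
                efe.predictive_entropy - efe.ambiguity, abs=1e-10
            )
            assert efe.G_total == pytest.approx(
                efe.info_gain + efe.utility + efe.param_info_gain, abs=1e-10
            )
            assert efe.info_gain >= 0
            assert efe.ambiguity >= 0
            assert efe.param_info_gain >= 0
            if efe.param_info_gain == 0:
                v = sum(
                    kl_value(pred.outcomes[k], model.preferences)
                    for k in range(pred.horizon)
                )
                assert efe.G_total == pytest.approx(v - efe.ambiguity, abs=1e-10)
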