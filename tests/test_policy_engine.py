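import numpy as np
import pytest

from planinf.engine import (
    PolicyPosterior,
    PolicyScores,
    action_marginal,
    iterate_policy_precision,
    policy_posterior,
    policy_prior,
    precision_posterior,
    select_action,
)
from planinf.model import (
    CategoricalDist,
    Policy,
    PrecisionBelief,
    default_precision_prior,
    softmax,
)


def kl(p, q):
    p = np.maximum(p, 1e-16)
    q = np.maximum(q, 1e-16)
    return float((p * np.log(p / q)).sum())


SINGLE_CTX = np.array([1.0])


class TestPolicyPrior:
    def test_equal_potentials_give_uniform(self):
        np.testing.assert_allclose(policy_prior(np.zeros(3)).weights, 1 / 3, atol=1e-14)

    def test_forced_value(self):
        np.testing.assert_allclose(
            policy_prior(np.array([np.log(2), 0.0])).weights, [2 / 3, 1 / 3], atol=1e-14
        )

    def test_shift_invariance(self):
        G = np.array([0.3, -1.2, 2.0])
        np.testing.assert_allclose(
            policy_prior(G).weights, policy_prior(G + 5.0).weights, atol=1e-12
        )


class TestPolicyPosterior:
    def test_constant_habit_reduces_to_fg_softmax(self):
        scores = PolicyScores(
            E=np.array([[2.0, 2.0]]), F=np.array([0.0, 1.0]), G=np.array([0.5, 0.0])
        )
        pp = policy_posterior(scores, default_precision_prior(), SINGLE_CTX)
        np.testing.assert_allclose(
            pp.weights.weights, softmax(scores.F + scores.G), atol=1e-12
        )

    def test_no_context_reduces_to_fg_softmax(self):
        scores = PolicyScores(E=None, F=np.array([0.0, 1.0]), G=np.array([0.5, 0.0]))
        pp = policy_posterior(scores, default_precision_prior(), None)
        np.testing.assert_allclose(
            pp.weights.weights, softmax(scores.F + scores.G), atol=1e-12
        )

    def test_degenerate_grid_single_context(self):
        b = 1.7
        scores = PolicyScores(
            E=np.array([[1.0, -0.5]]), F=np.array([0.2, 0.0]), G=np.array([0.0, 0.3])
        )
        pb = PrecisionBelief(np.array([b]), np.array([1.0]))
        pp = policy_posterior(scores, pb, SINGLE_CTX)
        np.testing.assert_allclose(
            pp.weights.weights,
            softmax(b * scores.E[0] + scores.F + scores.G),
            atol=1e-12,
        )

    def test_derived_softmax_value(self):
        scores = PolicyScores(
            E=np.array([[1.0, 0.0]]), F=np.zeros(2), G=np.array([0.0, np.log(2)])
        )
        pb = PrecisionBelief(np.array([1.0]), np.array([1.0]))
        pp = policy_posterior(scores, pb, SINGLE_CTX)
        np.testing.assert_allclose(pp.weights.weights, [0.5761, 0.4239], atol=1e-4)

    def test_context_expectation_outside_softmax(self):
        # two contexts with opposing habits: the posterior is the average of
        # per-context softmaxes, not the softmax of the averaged potential
        E = np.array([[3.0, 0.0], [0.0, 3.0]])
        scores = PolicyScores(E=E, F=np.zeros(2), G=np.zeros(2))
        pb = PrecisionBelief(np.array([1.0]), np.array([1.0]))
        ctx = np.array([0.5, 0.5])
        pp = policy_posterior(scores, pb, ctx)
        expected = 0.5 * softmax(E[0]) + 0.5 * softmax(E[1])
        np.testing.assert_allclose(pp.weights.weights, expected, atol=1e-12)

    def test_mixture_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            scores = PolicyScores(
                E=rng.normal(size=(2, 3)), F=rng.normal(size=3), G=rng.normal(size=3)
            )
            prior = default_precision_prior()
            ctx = rng.dirichlet(np.ones(2))
            pp = policy_posterior(scores, prior, ctx)
            np.testing.assert_allclose(
                pp.weights.weights, prior.weights @ pp.conditional, atol=1e-12
            )


class TestPrecisionPosterior:
    def test_constant_habit_returns_prior(self):
        scores = PolicyScores(
            E=np.zeros((1, 2)), F=np.array([0.0, 1.0]), G=np.array([1.0, 0.0])
        )
        prior = default_precision_prior()
        pp = policy_posterior(scores, prior, SINGLE_CTX)
        post = precision_posterior(scores, pp, prior, SINGLE_CTX)
        np.testing.assert_allclose(post.weights, prior.weights, atol=1e-12)

    def test_single_point_grid_is_point_mass(self):
        scores = PolicyScores(
            E=np.array([[1.0, 0.0]]), F=np.zeros(2), G=np.array([0.0, 1.0])
        )
        prior = PrecisionBelief(np.array([2.0]), np.array([1.0]))
        pp = policy_posterior(scores, prior, SINGLE_CTX)
        post = precision_posterior(scores, pp, prior, SINGLE_CTX)
        np.testing.assert_allclose(post.weights, [1.0], atol=1e-15)

    def test_matches_grid_enumeration_oracle(self):
        grid = np.array([0.5, 2.0])
        prior = PrecisionBelief(grid, np.array([0.5, 0.5]))
        E = np.array([[1.0, 0.0]])
        F = np.zeros(2)
        G = np.array([0.0, 1.0])
        scores = PolicyScores(E=E, F=F, G=G)
        pp = policy_posterior(scores, prior, SINGLE_CTX)
        # oracle: enumerate (pi, beta) explicitly
        cond = np.stack([softmax(b * E[0] + F + G) for b in grid])
        q_pi = prior.weights @ cond
        expected = np.zeros(2)
        for i in range(2):  # policy index
            w = prior.weights * cond[:, i]
            expected += q_pi[i] * (w / w.sum())
        post = precision_posterior(scores, pp, prior, SINGLE_CTX)
        np.testing.assert_allclose(post.weights, expected, atol=1e-12)


class TestIteratePolicyPrecision:
    def test_constant_habit_converges_immediately(self):
        scores = PolicyScores(
            E=np.full((1, 2), 3.0), F=np.array([0.0, 1.0]), G=np.array([0.2, 0.0])
        )
        prior = default_precision_prior()
        res = iterate_policy_precision(scores, prior, SINGLE_CTX)
        assert res.converged and res.iterations == 1
        np.testing.assert_allclose(
            res.policies.weights.weights, softmax(scores.F + scores.G), atol=1e-10
        )
        np.testing.assert_allclose(res.precision.weights, prior.weights, atol=1e-10)

    def test_returned_pair_is_a_fixed_point(self):
        rng = np.random.default_rng(3)
        scores = PolicyScores(
            E=rng.normal(size=(1, 4)), F=rng.normal(size=4), G=rng.normal(size=4)
        )
        prior = default_precision_prior()
        res = iterate_policy_precision(scores, prior, SINGLE_CTX, tol=1e-8)
        pp = policy_posterior(scores, res.precision, SINGLE_CTX)
        qb = precision_posterior(scores, pp, prior, SINGLE_CTX)
        assert np.abs(pp.weights.weights - res.policies.weights.weights).sum() < 1e-7
        assert np.abs(qb.weights - res.precision.weights).sum() < 1e-6

    def test_marginal_precision_never_exceeds_prior_under_conflict(self):
        """Sharp F+G conflicting with a habit: converged E[beta] <= prior E[beta]."""
        rng = np.random.default_rng(7)
        prior = default_precision_prior()
        checked = 0
        for _ in range(200):
            E = rng.normal(size=(1, 3))
            FG = 3.0 * rng.normal(size=3)
            if kl(softmax(FG), softmax(E[0])) <= 0.1:
                continue
            if softmax(FG).max() <= softmax(E[0]).max():
                continue  # require F+G to be the sharper potential
            scores = PolicyScores(E=E, F=FG, G=np.zeros(3))
            res = iterate_policy_precision(scores, prior, SINGLE_CTX)
            assert res.precision.mean() <= prior.mean() + 1e-9
            checked += 1
        assert checked >= 50

    def test_conditional_precision_drops_for_fg_dominant_policy(self):
        """Q(beta | pi) tilts to low beta for the policy the habit disfavours."""
        prior = default_precision_prior()
        E = np.array([[3.0, 0.0]])
        scores = PolicyScores(E=E, F=np.zeros(2), G=np.array([0.0, 3.0]))
        pp = policy_posterior(scores, prior, SINGLE_CTX)
        w = prior.weights[:, None] * pp.conditional  # joint over (beta, pi)
        w = w / w.sum(axis=0, keepdims=True)
        mean_fg_policy = float(prior.grid @ w[:, 1])  # policy favoured by G
        mean_habit_policy = float(prior.grid @ w[:, 0])
        assert mean_fg_policy < prior.mean() < mean_habit_policy

    def test_invalid_arguments(self):
        scores = PolicyScores(E=None, F=np.zeros(2), G=np.zeros(2))
        with pytest.raises(ValueError):
            iterate_policy_precision(scores, default_precision_prior(), max_iters=0)
        with pytest.raises(ValueError):
            iterate_policy_precision(scores, default_precision_prior(), tol=0.0)


class TestBetaInterpolation:
    """Clamping beta high/low drives the posterior to habit/free-energy limits."""

    def setup_method(self):
        self.scores = PolicyScores(
            E=np.array([[3.0, 0.0]]), F=np.zeros(2), G=np.array([0.0, 3.0])
        )

    def _posterior_at(self, b):
        pb = PrecisionBelief(np.array([b]), np.array([1.0]))
        return policy_posterior(self.scores, pb, SINGLE_CTX).weights.weights

    def test_large_beta_approaches_scaled_habit_softmax(self):
        kls = [
            kl(self._posterior_at(b), softmax(b * self.scores.E[0]))
            for b in (10.0, 100.0, 1000.0)
        ]
        assert kls[0] > kls[1] > kls[2] or kls[2] < 1e-12
        assert kls[-1] < 1e-3

    def test_small_beta_approaches_fg_softmax(self):
        kls = [
            kl(self._posterior_at(b), softmax(self.scores.F + self.scores.G))
            for b in (0.1, 0.01, 0.001)
        ]
        assert kls[-1] < 1e-3
        assert kls[-1] <= kls[0]


class TestSelectAction:
    POLICIES = [Policy((0, 1), id=0), Policy((1, 1), id=1), Policy((0, 0), id=2)]

    def _posterior(self, w):
        w = np.asarray(w, dtype=float)
        return PolicyPosterior(CategoricalDist(w), np.tile(w, (2, 1)))

    def test_point_mass_posterior_both_modes(self):
        post = self._posterior([0.0, 1.0, 0.0])
        for mode in ("argmax", "sample"):
            a = select_action(
                post, self.POLICIES, step=0, rng=np.random.default_rng(0), mode=mode
            )
            assert a == 1

    def test_agreeing_policies_are_deterministic(self):
        post = self._posterior([0.5, 0.0, 0.5])  # both use action 0 at step 0
        marg = action_marginal(post, self.POLICIES, step=0, n_actions=2)
        np.testing.assert_allclose(marg, [1.0, 0.0], atol=1e-14)

    def test_sampling_frequencies_match_marginal(self):
        post = self._posterior([0.3, 0.5, 0.2])
        marg = action_marginal(post, self.POLICIES, step=0, n_actions=2)
        rng = np.random.default_rng(123)
        n = 10_000
        draws = np.array(
            [select_action(post, self.POLICIES, 0, rng=rng) for _ in range(n)]
        )
        freq = (draws == 0).mean()
        se = np.sqrt(marg[0] * (1 - marg[0]) / n)
        assert abs(freq - marg[0]) < 3 * se

    def test_step_outside_horizon_raises(self):
        post = self._posterior([1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            select_action(post, self.POLICIES, step=5)
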