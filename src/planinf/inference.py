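"""Exact policy-conditioned state inference, prediction, and Dirichlet learning.

Inference is exact (forward-backward over the chain defined by the initial
state prior, the policy-selected transition kernels, and the likelihood), so
the variational free energy of a policy coincides with its log marginal
likelihood: F(pi) = ln P(o_< | pi).  No variational approximation is used.

Learning updates Dirichlet concentration counts over the likelihood, the
categorical analogue of Hebbian plasticity: the increment to counts[o, s] is
the product of the observed outcome (pre-synaptic) and the posterior state
belief (post-synaptic activity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    PROB_FLOOR,
    AgentModel,
    CategoricalDist,
    LikelihoodModel,
    Policy,
    log_stable,
)

__all__ = [
    "PosteriorBeliefs",
    "PredictiveBeliefs",
    "posterior_given_policy",
    "filter_forward",
    "predict",
    "predict_actions",
    "update_dirichlet",
]


@dataclass
class PosteriorBeliefs:
    """Smoothed and filtered state beliefs for one policy, plus F(pi).

    ``smoothed[t]`` is P(s_t | o_{0:T}, pi); ``filtered[t]`` is
    P(s_t | o_{0:t}, pi); ``log_evidence`` is F(pi) = ln P(o_{0:T} | pi).
    """

    smoothed: np.ndarray  # (T, S)
    filtered: np.ndarray  # (T, S)
    log_evidence: float


@dataclass
class PredictiveBeliefs:
    """Policy-conditioned predictions over future states and outcomes.

    ``states[k]`` is P(s_{t+k+1} | pi) and ``outcomes[k]`` the corresponding
    P(o_{t+k+1} | pi) = A @ states[k], for each remaining step of the policy.
    """

    states: np.ndarray  # (H, S)
    outcomes: np.ndarray  # (H, O)

    @property
    def horizon(self) -> int:
        return self.states.shape[0]


def _obs_likelihood(model: AgentModel, o: int) -> np.ndarray:
    if not (0 <= o < model.n_outcomes):
        raise ValueError(f"invalid outcome index {o} (model has {model.n_outcomes})")
    # floor so that impossible observations yield a very negative, finite F
    return np.maximum(model.likelihood.matrix[o, :], PROB_FLOOR)


def posterior_given_policy(
    model: AgentModel, policy: Policy, observations
) -> PosteriorBeliefs:
    """Exact filtering-smoothing posterior and F(pi) for an observed prefix.

    ``observations`` are outcome indices for timesteps 0..T; T may be at most
    the policy horizon.  Transitions between timesteps t and t+1 follow
    ``policy.actions[t]``.
    """
    obs = list(observations)
    if len(obs) == 0:
        raise ValueError("observations must be non-empty")
    if len(obs) > policy.horizon + 1:
        raise ValueError("more observations than the policy horizon admits")

    S = model.n_states
    T = len(obs)
    B = model.transitions.arrays
    alphas = np.empty((T, S))
    log_ev = 0.0
    prior = model.initial_states.weights
    for t, o in enumerate(obs):
        lik = _obs_likelihood(model, o)
        if t > 0:
            prior = B[policy.actions[t - 1]] @ alphas[t - 1]
        a = lik * prior
        c = a.sum()
        if c <= 0:  # fully degenerate prior x likelihood; keep F finite
            c = PROB_FLOOR
            a = np.full(S, 1.0 / S) * c
        log_ev += np.log(c)
        alphas[t] = a / c

    # backward pass (scaled)
    betas = np.ones((T, S))
    for t in range(T - 2, -1, -1):
        lik = _obs_likelihood(model, obs[t + 1])
        b = B[policy.actions[t]].T @ (lik * betas[t + 1])
        total = b.sum()
        betas[t] = b / (total if total > 0 else 1.0)

    smoothed = alphas * betas
    smoothed /= smoothed.sum(axis=1, keepdims=True)
    return PosteriorBeliefs(smoothed=smoothed, filtered=alphas, log_evidence=float(log_ev))


def filter_forward(model: AgentModel, actions, observations) -> np.ndarray:
    """Filtered state beliefs under an explicit executed action sequence.

    Used for learning: credit assignment conditions on the actions actually
    taken rather than on any hypothetical policy.  Returns an array of shape
    ``(len(observations), S)``.
    """
    p = Policy(tuple(actions) + (0,) * max(0, len(observations) - 1 - len(actions)), id=-1)
    return posterior_given_policy(model, p, observations).filtered


def predict_actions(
    model: AgentModel, actions, current_belief: np.ndarray
) -> PredictiveBeliefs:
    """Roll a state belief forward through an explicit action sequence."""
    qs = np.asarray(current_belief, dtype=float)
    if qs.shape != (model.n_states,):
        raise ValueError("current_belief dimension does not match the model")
    A = model.likelihood.matrix
    B = model.transitions.arrays
    states = np.empty((len(actions), model.n_states))
    for k, a in enumerate(actions):
        qs = B[a] @ qs
        qs = qs / qs.sum()
        states[k] = qs
    outcomes = states @ A.T
    return PredictiveBeliefs(states=states, outcomes=outcomes)


def predict(
    model: AgentModel, policy: Policy, current_belief: CategoricalDist
) -> PredictiveBeliefs:
    """Policy-conditioned predictive distributions over states and outcomes.

    A horizon-0 policy yields an empty prediction (not an error).
    """
    belief = (
        current_belief.weights
        if isinstance(current_belief, CategoricalDist)
        else np.asarray(current_belief, dtype=float)
    )
    return predict_actions(model, policy.actions, belief)


def update_dirichlet(
    likelihood: LikelihoodModel,
    observation: int,
    state_belief,
    rate: float = 1.0,
) -> LikelihoodModel:
    """Hebbian-style Dirichlet update of the likelihood counts.

    ``counts[observation, s] += rate * state_belief[s]`` except where
    ``frozen_mask`` is set (a disconnected entry's count cannot change); the
    matrix is re-derived as the column-normalised counts.  Returns a new
    :class:`LikelihoodModel`; the input is untouched.
    """
    if likelihood.counts is None:
        raise ValueError("update_dirichlet requires Dirichlet counts")
    belief = (
        state_belief.weights
        if isinstance(state_belief, CategoricalDist)
        else np.asarray(state_belief, dtype=float)
    )
    if not (0 <= observation < likelihood.n_outcomes):
        raise ValueError(f"invalid outcome index {observation}")
    counts = likelihood.counts.copy()
    delta = rate * belief
    if likelihood.frozen_mask is not None:
        delta = np.where(likelihood.frozen_mask[observation, :], 0.0, delta)
    counts[observation, :] += delta
    return LikelihoodModel.from_counts(
        counts,
        None if likelihood.frozen_mask is None else likelihood.frozen_mask.copy(),
    )
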