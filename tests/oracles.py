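"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive -- explicit summation over outcomes,
states, or whole state trajectories -- and shares no code path with the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.stats import beta as beta_dist


def enum_log_evidence(model, policy, observations) -> float:
    """ln P(o_{0:T} | pi) by explicit summation over all state trajectories."""
    S = model.n_states
    T = len(observations)
    A = model.likelihood.matrix
    B = model.transitions.arrays
    prior = model.initial_states.weights
    total = 0.0
    for traj in itertools.product(range(S), repeat=T):
        p = prior[traj[0]] * A[observations[0], traj[0]]
        for t in range(1, T):
            p *= B[policy.actions[t - 1], traj[t], traj[t - 1]]
            p *= A[observations[t], traj[t]]
        total += p
    return math.log(total)


def enum_smoothed(model, policy, observations) -> np.ndarray:
    """Per-timestep posterior state marginals by trajectory enumeration."""
    S = model.n_states
    T = len(observations)
    A = model.likelihood.matrix
    B = model.transitions.arrays
    prior = model.initial_states.weights
    marg = np.zeros((T, S))
    for traj in itertools.product(range(S), repeat=T):
        p = prior[traj[0]] * A[observations[0], traj[0]]
        for t in range(1, T):
            p *= B[policy.actions[t - 1], traj[t], traj[t - 1]]
            p *= A[observations[t], traj[t]]
        for t, s in enumerate(traj):
            marg[t, s] += p
    return marg / marg.sum(axis=1, keepdims=True)


def enum_predictions(model, actions, belief) -> np.ndarray:
    """P(s_{t+k} | pi) by summing over all state trajectories."""
    S = model.n_states
    B = model.transitions.arrays
    H = len(actions)
    marg = np.zeros((H, S))
    for traj in itertools.product(range(S), repeat=H + 1):
        p = belief[traj[0]]
        for k in range(H):
            p *= B[actions[k], traj[k + 1], traj[k]]
        for k in range(H):
            marg[k, traj[k + 1]] += p
    return marg / marg.sum(axis=1, keepdims=True)


def mi_double_sum(A: np.ndarray, qs: np.ndarray) -> float:
    """Mutual information by direct double summation over (o, s)."""
    O, S = A.shape
    po = A @ qs
    total = 0.0
    for o in range(O):
        for s in range(S):
            j = A[o, s] * qs[s]
            if j > 0:
                total += j * math.log(j / (po[o] * qs[s]))
    return total


def kl(p: np.ndarray, q: np.ndarray) -> float:
    """Direct-summation KL divergence."""
    total = 0.0
    for pi_, qi in zip(p, q):
        if pi_ > 0:
            total += pi_ * math.log(pi_ / qi)
    return total


def beta_kl_quad(a1: float, b1: float, a0: float, b0: float) -> float:
    """KL[Beta(a1,b1) || Beta(a0,b0)] by numerical integration."""

    def integrand(x):
        p = beta_dist.pdf(x, a1, b1)
        if p <= 0:
            return 0.0
        return p * (beta_dist.logpdf(x, a1, b1) - beta_dist.logpdf(x, a0, b0))

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return val
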