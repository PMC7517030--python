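"""Policy priors/posteriors, reciprocal precision inference, action selection.

The policy prior is a softmax of the expected free energy alone,
``P(pi) = softmax(G)``.  The posterior additionally incorporates the evidence
already accumulated for each policy (the variational free energy F) and, when
a slower timescale supplies a habit potential E, a precision-weighted mixture:

    Q(pi | beta) = E_{Q(context)}[ softmax_pi( beta * E(pi, context) + F + G ) ]
    Q(pi)        = E_{Q(beta)}[ Q(pi | beta) ]

with the softmax taken per context state and then averaged (the expectation
sits outside the softmax).  The precision belief is itself inferred from the
policy posterior, and the two updates are iterated to a fixed point:

    Q(beta | pi) = softmax_beta( ln Q(pi | beta) + ln P(beta) )
    Q(beta)      = E_{Q(pi)}[ Q(beta | pi) ]

Large beta lets the habit dominate (contextually inappropriate policies are
suppressed -- "what not to do"); small beta lets F + G dominate.  Logs report
``1 / E[beta]`` as ``precision_inverse``, the package's dopamine analogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    PROB_FLOOR,
    CategoricalDist,
    Policy,
    PrecisionBelief,
    softmax,
    log_stable,
)

__all__ = [
    "PolicyScores",
    "PolicyPosterior",
    "PrecisionLoopResult",
    "policy_prior",
    "policy_posterior",
    "precision_posterior",
    "iterate_policy_precision",
    "select_action",
    "action_marginal",
]


@dataclass
class PolicyScores:
    """Per-policy potentials: habit E (context x policy), F and G (policy,).

    ``E`` may be None when no habit/context applies.
    """

    E: Optional[np.ndarray]
    F: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        if self.E is not None:
            self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.F = np.asarray(self.F, dtype=float)
        self.G = np.asarray(self.G, dtype=float)


@dataclass
class PolicyPosterior:
    """Marginal policy weights plus the per-beta-gridpoint conditionals."""

    weights: CategoricalDist
    conditional: np.ndarray  # (n_beta, n_policies)


@dataclass
class PrecisionLoopResult:
    policies: PolicyPosterior
    precision: PrecisionBelief
    iterations: int
    converged: bool


def policy_prior(G: np.ndarray) -> CategoricalDist:
    """Prior over policies: softmax of the expected free energy."""
    return CategoricalDist(softmax(G))


def policy_posterior(
    scores: PolicyScores,
    precision: PrecisionBelief,
    context_belief: Optional[np.ndarray] = None,
) -> PolicyPosterior:
    """Precision-weighted policy posterior.

    With no habit or context the conditional collapses to softmax(F + G) at
    every beta gridpoint.
    """
    fg = scores.F + scores.G
    n_beta = precision.grid.shape[0]
    if scores.E is None or context_belief is None:
        base = softmax(fg)
        conditional = np.tile(base, (n_beta, 1))
    else:
        ctx = (
            context_belief.weights
            if isinstance(context_belief, CategoricalDist)
            else np.asarray(context_belief, dtype=float)
        )
        if ctx.shape[0] != scores.E.shape[0]:
            raise ValueError(
                "context belief dimension does not match the habit context axis"
            )
        # potentials[b, c, pi] = beta_b * E[c, pi] + F[pi] + G[pi]
        pot = precision.grid[:, None, None] * scores.E[None, :, :] + fg[None, None, :]
        per_context = softmax(pot, axis=2)  # softmax inside the expectation
        conditional = np.einsum("c,bcp->bp", ctx, per_context)
    weights = precision.weights @ conditional
    return PolicyPosterior(CategoricalDist(weights / weights.sum()), conditional)


def precision_posterior(
    scores: PolicyScores,
    posterior_policies: PolicyPosterior,
    prior: PrecisionBelief,
    context_belief: Optional[np.ndarray] = None,
) -> PrecisionBelief:
    """Posterior over beta: Q(beta) = E_{Q(pi)}[ softmax_b(ln Q(pi|b) + ln P(b)) ].

    Evaluated exactly on the grid.  When the conditional is beta-independent
    (e.g. a flat habit) the posterior equals the prior.
    """
    cond = posterior_policies.conditional  # (B, P)
    log_post = log_stable(cond) + log_stable(prior.weights)[:, None]
    per_policy = softmax(log_post, axis=0)  # (B, P), normalised over beta
    qb = per_policy @ posterior_policies.weights.weights
    return PrecisionBelief(prior.grid.copy(), qb / qb.sum())


def iterate_policy_precision(
    scores: PolicyScores,
    prior_precision: PrecisionBelief,
    context_belief: Optional[np.ndarray] = None,
    max_iters: int = 16,
    tol: float = 1e-6,
    damping: float = 0.5,
) -> PrecisionLoopResult:
    """Alternate policy and precision updates to a reciprocal fixed point.

    The precision update is damped (``new = damping*old + (1-damping)*proposed``)
    to prevent oscillation; the fixed points of the damped and raw updates
    coincide.  Non-convergence within ``max_iters`` is flagged, not raised.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    q_beta = prior_precision.copy()
    prev_pol: Optional[np.ndarray] = None
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        pp = policy_posterior(scores, q_beta, context_belief)
        proposed = precision_posterior(scores, pp, prior_precision, context_belief)
        new_w = damping * q_beta.weights + (1.0 - damping) * proposed.weights
        d_beta = float(np.abs(new_w - q_beta.weights).sum())
        d_pol = (
            float(np.abs(pp.weights.weights - prev_pol).sum())
            if prev_pol is not None
            else 0.0
        )
        q_beta = PrecisionBelief(q_beta.grid, new_w / new_w.sum())
        prev_pol = pp.weights.weights
        if d_beta < tol and d_pol < tol:
            converged = True
            break
    # final policy posterior consistent with the returned precision belief
    pp = policy_posterior(scores, q_beta, context_belief)
    return PrecisionLoopResult(pp, q_beta, it, converged)


def action_marginal(
    posterior: PolicyPosterior, policies: list[Policy], step: int, n_actions: int
) -> np.ndarray:
    """Marginal distribution over this step's action under the policy posterior."""
    if not policies:
        raise ValueError("no policies supplied")
    if not (0 <= step < policies[0].horizon):
        raise ValueError(f"step {step} outside the policy horizon")
    w = posterior.weights.weights
    marg = np.zeros(n_actions)
    for p, weight in zip(policies, w):
        marg[p.actions[step]] += weight
    return marg / marg.sum()


def select_action(
    posterior: PolicyPosterior,
    policies: list[Policy],
    step: int,
    rng: Optional[np.random.Generator] = None,
    mode: str = "sample",
) -> int:
    """Select this step's action from the policy posterior.

    ``sample`` draws from the action marginal with the supplied generator;
    ``argmax`` is deterministic (lowest index on ties).
    """
    n_actions = max(max(p.actions) for p in policies) + 1
    marg = action_marginal(posterior, policies, step, n_actions)
    if mode == "argmax":
        return int(np.argmax(marg))
    if mode == "sample":
        if rng is None:
            rng = np.random.default_rng()
        return int(rng.choice(n_actions, p=marg))
    raise ValueError(f"unknown selection mode {mode!r}")
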