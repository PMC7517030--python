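"""Per-policy objective functions: the ingredients of the policy prior.

The expected free energy ``G`` of a policy is, in this package's sign
convention, a quantity to be **maximised**:

    G(pi) = H[P(o|pi)] + E_{P(o|pi)}[ln P(o|C)] - E_{P(s|pi)}[H[P(o|s)]]
          = info_gain(pi) + utility(pi)
          = value(pi) - ambiguity(pi)

where ``info_gain`` is the mutual information between future states and
outcomes (salience), ``utility`` the expected log-preference, ``value`` the
negative KL from predicted to preferred outcomes (the KL-control value), and
``ambiguity`` the expected conditional entropy of outcomes given states.
When the likelihood carries Dirichlet counts, an additional novelty term --
the expected KL between post- and pre-update Dirichlet beliefs about the
likelihood parameters -- enters G additively (``param_info_gain``).

Multi-step policies sum per-timestep contributions.  All quantities are in
nats.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.special import digamma, gammaln

from .model import AgentModel, CategoricalDist, LikelihoodModel, PreferenceModel, log_stable
from .inference import PredictiveBeliefs

__all__ = [
    "EFEBreakdown",
    "mutual_information",
    "kl_value",
    "ambiguity",
    "parameter_info_gain",
    "expected_free_energy",
    "dirichlet_kl",
]

MI_METHODS = ("joint_kl", "posterior_divergence", "entropy_difference")


@dataclass
class EFEBreakdown:
    """The components of a policy's expected free energy (all in nats).

    Invariants: ``info_gain = predictive_entropy - ambiguity`` and
    ``G_total = info_gain + utility + param_info_gain``.
    """

    predictive_entropy: float
    utility: float
    ambiguity: float
    info_gain: float
    param_info_gain: float
    G_total: float


def _entropy(p: np.ndarray) -> float:
    return float(-(p * log_stable(p)).sum())


def _joint(A: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """P(o, s | pi) = P(o|s) P(s|pi) as an (O, S) array."""
    return A * qs[None, :]


def _mi_one_step(A: np.ndarray, qs: np.ndarray, method: str) -> float:
    joint = _joint(A, qs)
    po = joint.sum(axis=1)
    if method == "joint_kl":
        prod = po[:, None] * qs[None, :]
        val = float((joint * (log_stable(joint) - log_stable(prod))).sum())
    elif method == "posterior_divergence":
        val = 0.0
        for o in range(A.shape[0]):
            if po[o] <= 0:
                continue
            post = joint[o, :] / po[o]
            val += po[o] * float((post * (log_stable(post) - log_stable(qs))).sum())
    elif method == "entropy_difference":
        cond = -(A * log_stable(A)).sum(axis=0)  # H[P(o|s)] per state
        val = _entropy(po) - float(qs @ cond)
    else:
        raise ValueError(
            f"unknown method {method!r}; expected one of {MI_METHODS}"
        )
    return max(val, 0.0)


def mutual_information(
    predictive: PredictiveBeliefs,
    likelihood: LikelihoodModel,
    method: str = "entropy_difference",
) -> float:
    """Expected information gain I(pi) about states, in nats.

    Three algebraically equivalent factorisations are available:

    * ``joint_kl`` -- KL between the predictive joint and the product of its
      marginals;
    * ``posterior_divergence`` -- the outcome-averaged KL from prior to
      posterior state beliefs (the "expected belief update");
    * ``entropy_difference`` -- predictive entropy minus ambiguity.

    Contributions are summed over the remaining policy timesteps.  The value
    is zero exactly when outcomes carry no information about states (e.g. a
    likelihood with identical columns).
    """
    if method not in MI_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {MI_METHODS}")
    A = likelihood.matrix
    if predictive.horizon and predictive.states.shape[1] != A.shape[1]:
        raise ValueError("predictive beliefs and likelihood are inconsistent")
    return float(
        sum(_mi_one_step(A, predictive.states[k], method) for k in range(predictive.horizon))
    )


def kl_value(predictive_outcomes, preferences: PreferenceModel) -> float:
    """KL-control value V(pi) = -KL[P(o|pi) || P(o|C)] <= 0 for one timestep.

    Zero exactly when the predicted outcome distribution matches the
    normalised preference distribution.
    """
    po = (
        predictive_outcomes.weights
        if isinstance(predictive_outcomes, CategoricalDist)
        else np.asarray(predictive_outcomes, dtype=float)
    )
    logc = preferences.log_dist()
    if po.shape != logc.shape:
        raise ValueError("outcome prediction and preferences differ in length")
    kl = float((po * (log_stable(po) - logc)).sum())
    return -max(kl, 0.0)


def ambiguity(likelihood: LikelihoodModel, state_prediction) -> float:
    """Expected conditional entropy of outcomes given states (>= 0)."""
    qs = (
        state_prediction.weights
        if isinstance(state_prediction, CategoricalDist)
        else np.asarray(state_prediction, dtype=float)
    )
    A = likelihood.matrix
    if qs.shape[0] != A.shape[1]:
        raise ValueError("state prediction and likelihood differ in dimension")
    cond = -(A * log_stable(A)).sum(axis=0)
    return max(float(qs @ cond), 0.0)


def dirichlet_kl(alpha_p: np.ndarray, alpha_q: np.ndarray) -> float:
    """KL[Dir(alpha_p) || Dir(alpha_q)] in closed form."""
    ap = np.asarray(alpha_p, dtype=float)
    aq = np.asarray(alpha_q, dtype=float)
    ap0 = ap.sum()
    aq0 = aq.sum()
    return float(
        gammaln(ap0)
        - gammaln(ap).sum()
        - gammaln(aq0)
        + gammaln(aq).sum()
        + ((ap - aq) * (digamma(ap) - digamma(ap0))).sum()
    )


def parameter_info_gain(
    likelihood: LikelihoodModel,
    predictive: PredictiveBeliefs,
    rate: float = 1.0,
) -> float:
    """Novelty: expected Dirichlet belief change about likelihood parameters.

    For each remaining timestep the expected KL between the post-update and
    pre-update Dirichlet column is averaged under the predictive joint
    P(s|pi) P(o|s); entries under ``frozen_mask`` contribute zero (their
    counts cannot change).  Returns 0 when no counts are present -- the
    parameters are then treated as known.
    """
    if likelihood.counts is None:
        return 0.0
    A = likelihood.matrix
    counts = likelihood.counts
    frozen = likelihood.frozen_mask
    O, S = A.shape

    # KL of adding `rate` to entry (o, s), per column
    kl_table = np.zeros((O, S))
    for s in range(S):
        col = counts[:, s]
        for o in range(O):
            if frozen is not None and frozen[o, s]:
                continue
            post = col.copy()
            post[o] += rate
            kl_table[o, s] = dirichlet_kl(post, col)

    total = 0.0
    for k in range(predictive.horizon):
        qs = predictive.states[k]
        total += float((A * qs[None, :] * kl_table).sum())
    return max(total, 0.0)


def expected_free_energy(
    model: AgentModel,
    predictive: PredictiveBeliefs,
    learning_rate: float = 1.0,
) -> EFEBreakdown:
    """Full expected-free-energy breakdown for one policy's predictions.

    Fills every component; ``G_total`` is the potential to be maximised.
    """
    A = model.likelihood.matrix
    logc = model.preferences.log_dist()
    pe = 0.0
    util = 0.0
    amb = 0.0
    for k in range(predictive.horizon):
        po = predictive.outcomes[k]
        pe += _entropy(po)
        util += float(po @ logc)
        amb += ambiguity(model.likelihood, predictive.states[k])
    ig = max(pe - amb, 0.0)
    pig = parameter_info_gain(model.likelihood, predictive, rate=learning_rate)
    return EFEBreakdown(
        predictive_entropy=pe,
        utility=util,
        ambiguity=amb,
        info_gain=ig,
        param_info_gain=pig,
        G_total=ig + util + pig,
    )
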