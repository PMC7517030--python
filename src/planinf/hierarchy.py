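"""Two-level deep temporal models.

The higher (slower) level's state belief conditions the lower level through a
descending message: it selects the habit context for the policy engine and may
supply empirical priors for the lower level's preferences and initial states.
After a full lower-level trial, the policy-averaged final state belief ascends
as a *soft observation* for the higher level -- lower-level states act as if
they were observations from the perspective of the higher level, with one
higher-level timestep spanning exactly one full lower-level trial.

Ascending messages enter the higher level as belief-weighted likelihood
(soft evidence); an optional hard-observation mode collapses the message to
its argmax outcome (lowest index on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import AgentModel, CategoricalDist, validate_model
from .inference import PosteriorBeliefs
from .engine import PolicyPosterior

__all__ = [
    "LevelLink",
    "DeepModel",
    "DescendingMessage",
    "descending_message",
    "ascending_message",
    "level2_update",
    "run_hierarchical_trial",
]


@dataclass
class LevelLink:
    """How level-2 states condition level 1.

    ``context_map[s2]`` gives the level-1 habit-context index for each level-2
    state.  ``preferences`` (optional, shape ``(S2, O1)``) and
    ``initial_states`` (optional, shape ``(S2, S1)``) supply per-level-2-state
    empirical priors for the lower level, blended under the level-2 belief.
    """

    context_map: np.ndarray
    preferences: Optional[np.ndarray] = None
    initial_states: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.context_map = np.asarray(self.context_map, dtype=int)
        if self.preferences is not None:
            self.preferences = np.asarray(self.preferences, dtype=float)
        if self.initial_states is not None:
            self.initial_states = np.asarray(self.initial_states, dtype=float)


@dataclass
class DeepModel:
    """Two stacked agent models; one level-2 step wraps one level-1 trial."""

    level1: AgentModel
    level2: AgentModel
    link: LevelLink

    def copy(self) -> "DeepModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def violations(self) -> list[str]:
        out = []
        for name, m in (("level1", self.level1), ("level2", self.level2)):
            out += [f"{name}.{v}" for v in validate_model(m)]
        S2 = self.level2.n_states
        if self.link.context_map.shape != (S2,):
            out.append("link.context_map: length differs from level-2 states")
        elif np.any(self.link.context_map < 0) or np.any(
            self.link.context_map >= self.level1.habits.n_contexts
        ):
            out.append("link.context_map: contains an invalid context index")
        if self.link.preferences is not None and self.link.preferences.shape != (
            S2,
            self.level1.n_outcomes,
        ):
            out.append("link.preferences: shape differs from (S2, level-1 outcomes)")
        if self.link.initial_states is not None and self.link.initial_states.shape != (
            S2,
            self.level1.n_states,
        ):
            out.append("link.initial_states: shape differs from (S2, level-1 states)")
        if self.level2.n_outcomes != self.level1.n_states:
            out.append(
                "level2: outcome space must equal the level-1 state space "
                "(ascending messages are level-1 state beliefs)"
            )
        return out


@dataclass
class DescendingMessage:
    """Level-2 conditioning of level 1 for one trial."""

    context_belief: np.ndarray  # over level-1 habit contexts
    log_pref: Optional[np.ndarray] = None  # empirical prior over level-1 outcomes
    initial_states: Optional[np.ndarray] = None  # empirical level-1 state prior


def descending_message(level2_belief, deep: DeepModel) -> DescendingMessage:
    """Project the level-2 state belief down onto level-1 priors.

    The context distribution aggregates level-2 belief mass through
    ``context_map``; linked preference vectors and initial-state priors are
    blended linearly under the level-2 belief (log-preferences mix linearly,
    i.e. geometrically on the probability scale).
    """
    b2 = (
        level2_belief.weights
        if isinstance(level2_belief, CategoricalDist)
        else np.asarray(level2_belief, dtype=float)
    )
    n_ctx = deep.level1.habits.n_contexts
    ctx = np.zeros(n_ctx)
    np.add.at(ctx, deep.link.context_map, b2)
    ctx = ctx / ctx.sum()
    log_pref = None
    if deep.link.preferences is not None:
        log_pref = b2 @ deep.link.preferences
    init = None
    if deep.link.initial_states is not None:
        init = b2 @ deep.link.initial_states
        init = init / init.sum()
    return DescendingMessage(context_belief=ctx, log_pref=log_pref, initial_states=init)


def ascending_message(
    level1_posteriors: list[PosteriorBeliefs],
    level1_policy_posterior: PolicyPosterior,
) -> np.ndarray:
    """Policy-averaged final smoothed state belief, the level-2 soft observation."""
    w = level1_policy_posterior.weights.weights
    if len(level1_posteriors) != w.shape[0]:
        raise ValueError("one posterior per policy is required")
    msg = sum(
        weight * post.smoothed[-1] for weight, post in zip(w, level1_posteriors)
    )
    msg = np.asarray(msg, dtype=float)
    return msg / msg.sum()


def level2_update(
    level2: AgentModel,
    belief: np.ndarray,
    message: np.ndarray,
    mode: str = "soft",
) -> np.ndarray:
    """Update the level-2 state belief from an ascending message.

    ``soft``: likelihood-weighting, L(s2) = sum_o message[o] * A2[o, s2];
    ``hard``: condition on the message's argmax outcome (lowest-index ties).
    """
    A2 = level2.likelihood.matrix
    if message.shape[0] != A2.shape[0]:
        raise ValueError("ascending message length differs from level-2 outcomes")
    if mode == "soft":
        lik = message @ A2
    elif mode == "hard":
        lik = A2[int(np.argmax(message)), :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    post = np.asarray(belief, dtype=float) * np.maximum(lik, 0.0)
    total = post.sum()
    if total <= 0:
        post = np.asarray(belief, dtype=float).copy()
        total = post.sum()
    return post / total


def run_hierarchical_trial(deep: DeepModel, environment, seed: int, **kwargs):
    """One level-2 step wrapping a full level-1 trial.

    Convenience wrapper over :func:`planinf.simulate.run_trials` with
    ``n_trials=1``; returns the single :class:`~planinf.simulate.TrialRecord`.
    """
    from .simulate import run_trials

    return run_trials(deep, environment, n_trials=1, seed=seed, **kwargs)[0]
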