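"""Seeded generators for the synthetic tasks the engine's claims are staged on.

Each generator returns a matched ``(model, environment)`` pair: the model is
the agent's *generative model*, the environment the *generative process* that
actually emits outcomes.  Generators are deterministic given their seed.

Three tasks:

* **Saccade task** -- gaze locations holding unknown visual categories; with a
  flat (unlearned) likelihood and flat preferences, exploration is driven
  purely by parameter information gain (novelty).  Half the locations are
  labelled "left", half "right", which is all the hemispatial geometry the
  neglect experiment needs.
* **Context-choice task** -- a two-level model: a slow context state, a cue
  that (validly with probability ``p_cue_valid``) signals it, and a choice
  whose interoceptive consequence ("juice") depends on matching the context.
* **Repetition task** -- copy-me-N-times: states count completed repetitions,
  preferences favour stopping at exactly ``n_required``, and observations
  report the agent's own progress so the variational free energy accrues
  evidence for whatever policy is under way.
"""

from __future__ import annotations

import numpy as np

from .model import (
    AgentModel,
    CategoricalDist,
    HabitPrior,
    LikelihoodModel,
    Policy,
    PreferenceModel,
    TransitionModel,
    default_precision_prior,
)
from .hierarchy import DeepModel, LevelLink

__all__ = [
    "Environment",
    "SaccadeEnvironment",
    "ContextChoiceEnvironment",
    "RepetitionEnvironment",
    "make_saccade_task",
    "make_context_choice_task",
    "make_repetition_task",
    "make_task",
    "TASKS",
]


class Environment:
    """The generative process paired with an agent model.

    ``reset(rng)`` starts a trial (drawing any trial-level latent variables
    from ``rng``) and returns the initial outcome index; ``emit(action)``
    advances the hidden state and returns the next outcome.  ``labels``
    carries semantic tags (hemifield sides, null actions, ...) consumed by the
    phenotype statistics.
    """

    n_outcomes: int = 0
    labels: dict = {}

    def reset(self, rng: np.random.Generator) -> int:  # pragma: no cover
        raise NotImplementedError

    def emit(self, action: int) -> int:  # pragma: no cover
        raise NotImplementedError


class SaccadeEnvironment(Environment):
    """A fixed random scene: one category per gaze location."""

    def __init__(self, scene: np.ndarray, n_categories: int, labels: dict):
        self.scene = np.asarray(scene, dtype=int)
        self.n_outcomes = n_categories + 1
        self.labels = labels

    def reset(self, rng: np.random.Generator) -> int:
        return 0  # fixation point

    def emit(self, action: int) -> int:
        return 1 + int(self.scene[action])


class RepetitionEnvironment(Environment):
    """Counts completed repetitions; observations report the count."""

    def __init__(self, horizon: int, labels: dict):
        self.horizon = horizon
        self.n_outcomes = horizon + 1
        self.labels = labels
        self._count = 0

    def reset(self, rng: np.random.Generator) -> int:
        self._count = 0
        return 0

    def emit(self, action: int) -> int:
        if action == 1:
            self._count = min(self._count + 1, self.horizon)
        return self._count


class ContextChoiceEnvironment(Environment):
    """Cue -> delay -> choice; juice only follows the context-matching choice."""

    CUE_A, CUE_B, BLANK, JUICE, NO_JUICE = range(5)

    def __init__(self, p_cue_valid: float, labels: dict):
        self.p_cue_valid = p_cue_valid
        self.n_outcomes = 5
        self.labels = labels
        self.context = 0
        self.trial_contexts: list[int] = []

    def reset(self, rng: np.random.Generator) -> int:
        self.context = int(rng.integers(2))
        self.trial_contexts.append(self.context)
        valid = rng.random() < self.p_cue_valid
        cue_ctx = self.context if valid else 1 - self.context
        return self.CUE_A if cue_ctx == 0 else self.CUE_B

    def emit(self, action: int) -> int:
        if action == 0:  # wait
            return self.BLANK
        chosen = action - 1  # 1 -> target 0, 2 -> target 1
        return self.JUICE if chosen == self.context else self.NO_JUICE


def make_saccade_task(
    n_locations: int = 4,
    n_categories: int = 3,
    counts_scale: float = 0.5,
    seed: int = 0,
) -> tuple[AgentModel, SaccadeEnvironment]:
    """Visual-scene exploration driven by novelty.

    States are a start fixation plus ``n_locations`` gaze locations (the
    first half labelled "left", the rest "right"); policies are single-step
    saccades, one per location.  Location likelihood columns start as flat
    Dirichlet counts at ``counts_scale`` (the scene is unknown), so the only
    asymmetry in G across saccades is each location's remaining novelty.
    The environment draws a fixed random scene from ``seed``.
    """
    if n_locations < 2 or n_locations % 2:
        raise ValueError("n_locations must be an even integer >= 2")
    if counts_scale <= 0:
        raise ValueError("counts_scale must be positive")
    S = n_locations + 1  # state 0 = start fixation
    O = n_categories + 1  # outcome 0 = fixation point
    counts = np.full((O, S), 1e-6)
    counts[0, 0] = 1e6  # the start state's percept is known
    counts[1:, 1:] = counts_scale
    likelihood = LikelihoodModel.from_counts(counts)

    B = np.zeros((n_locations, S, S))
    for j in range(n_locations):
        B[j, j + 1, :] = 1.0  # saccade to location j from anywhere

    init = np.zeros(S)
    init[0] = 1.0
    policies = [Policy((j,), id=j) for j in range(n_locations)]

    model = AgentModel(
        likelihood=likelihood,
        transitions=TransitionModel(B),
        preferences=PreferenceModel(np.zeros(O)),
        initial_states=CategoricalDist(init),
        habits=HabitPrior(np.zeros((1, n_locations))),
        precision_prior=default_precision_prior(),
        policies=policies,
    )

    rng = np.random.default_rng(seed)
    scene = rng.integers(n_categories, size=n_locations)
    side = {j: ("left" if j < n_locations // 2 else "right") for j in range(n_locations)}
    labels = {
        "task": "saccade",
        "action_side": side,
        "null_actions": [],
        "locations": {j: f"loc{j}" for j in range(n_locations)},
    }
    return model, SaccadeEnvironment(scene, n_categories, labels)


def left_hemifield_mask(model: AgentModel, n_locations: int) -> np.ndarray:
    """Likelihood mask covering every left-labelled location's column."""
    mask = np.zeros_like(model.likelihood.matrix, dtype=bool)
    mask[:, 1 : 1 + n_locations // 2] = True
    return mask


def make_repetition_task(
    n_required: int = 3,
    horizon: int = 8,
    seed: int = 0,
    pref_strength: float = 3.0,
    obs_noise: float = 0.02,
) -> tuple[AgentModel, RepetitionEnvironment]:
    """Copy-me-``n_required``-times.

    States (and outcomes) count completed repetitions, 0..horizon; actions
    are stop (0, the null action) and repeat (1); the policy set is
    "repeat k times then stop" for k = 0..horizon.  Preferences put
    ``pref_strength`` nats on observing exactly ``n_required`` repetitions.
    The near-identity likelihood (``obs_noise`` leakage) reports the agent's
    own progress, so F accrues evidence for the policy being enacted.
    """
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    if horizon <= n_required:
        raise ValueError("horizon must exceed n_required")
    S = horizon + 1
    A_mat = np.full((S, S), obs_noise / (S - 1))
    np.fill_diagonal(A_mat, 1.0 - obs_noise)
    B = np.zeros((2, S, S))
    B[0] = np.eye(S)  # stop: count unchanged
    for c in range(S):
        B[1, min(c + 1, horizon), c] = 1.0  # repeat: count + 1 (capped)

    log_pref = np.zeros(S)
    log_pref[n_required] = pref_strength
    init = np.zeros(S)
    init[0] = 1.0
    policies = [
        Policy((1,) * k + (0,) * (horizon - k), id=k) for k in range(horizon + 1)
    ]
    model = AgentModel(
        likelihood=LikelihoodModel(A_mat),
        transitions=TransitionModel(B),
        preferences=PreferenceModel(log_pref),
        initial_states=CategoricalDist(init),
        habits=HabitPrior(np.zeros((1, len(policies)))),
        precision_prior=default_precision_prior(),
        policies=policies,
    )
    labels = {
        "task": "repetition",
        "action_side": {},
        "null_actions": [0],
        "repeat_action": 1,
        "n_required": n_required,
    }
    return model, RepetitionEnvironment(horizon, labels)


def make_context_choice_task(
    p_cue_valid: float = 0.9,
    reward_pref: float = 4.0,
    seed: int = 0,
) -> tuple[DeepModel, ContextChoiceEnvironment]:
    """Cued two-context choice with an interoceptive reward, as a deep model.

    Level 2 holds the slowly varying context (redrawn each trial); level 1
    runs one trial: cue observation, a delay, then a choice between two
    targets, with "juice" emitted only after the context-matching choice.
    The cue signals the true context with probability ``p_cue_valid``;
    preferences give juice a ``reward_pref``-nat advantage over its absence.
    """
    if not (0.5 < p_cue_valid <= 1.0):
        raise ValueError("p_cue_valid must lie in (0.5, 1]")
    v = p_cue_valid
    # level-1 states: context (2) x stage {cue, delay, choseL, choseR}
    S1, O1, A1 = 8, 5, 3
    sidx = lambda c, st: c * 4 + st
    A_mat = np.zeros((O1, S1))
    for c in range(2):
        A_mat[ContextChoiceEnvironment.CUE_A, sidx(c, 0)] = v if c == 0 else 1 - v
        A_mat[ContextChoiceEnvironment.CUE_B, sidx(c, 0)] = 1 - v if c == 0 else v
        A_mat[ContextChoiceEnvironment.BLANK, sidx(c, 1)] = 1.0
        for choice, st in ((0, 2), (1, 3)):
            o = (
                ContextChoiceEnvironment.JUICE
                if choice == c
                else ContextChoiceEnvironment.NO_JUICE
            )
            A_mat[o, sidx(c, st)] = 1.0

    B = np.zeros((A1, S1, S1))
    for c in range(2):
        # wait: cue -> delay; everything else absorbing
        B[0, sidx(c, 1), sidx(c, 0)] = 1.0
        B[0, sidx(c, 1), sidx(c, 1)] = 1.0
        B[0, sidx(c, 2), sidx(c, 2)] = 1.0
        B[0, sidx(c, 3), sidx(c, 3)] = 1.0
        for a, st in ((1, 2), (2, 3)):
            B[a, sidx(c, st), sidx(c, 0)] = 1.0
            B[a, sidx(c, st), sidx(c, 1)] = 1.0
            B[a, sidx(c, 2), sidx(c, 2)] = 1.0
            B[a, sidx(c, 3), sidx(c, 3)] = 1.0

    log_pref = np.zeros(O1)
    log_pref[ContextChoiceEnvironment.JUICE] = reward_pref
    init1 = np.zeros(S1)
    init1[[sidx(0, 0), sidx(1, 0)]] = 0.5
    policies1 = [Policy((0, 1), id=0), Policy((0, 2), id=1)]
    level1 = AgentModel(
        likelihood=LikelihoodModel(A_mat),
        transitions=TransitionModel(B),
        preferences=PreferenceModel(log_pref),
        initial_states=CategoricalDist(init1),
        habits=HabitPrior(np.zeros((2, 2))),
        precision_prior=default_precision_prior(),
        policies=policies1,
    )

    # level 2: the context; its "outcomes" are level-1 states
    A2 = np.zeros((S1, 2))
    for c in range(2):
        A2[c * 4 : (c + 1) * 4, c] = 0.25
    level2 = AgentModel(
        likelihood=LikelihoodModel(A2),
        transitions=TransitionModel(np.full((1, 2, 2), 0.5)),  # context redrawn
        preferences=PreferenceModel(np.zeros(S1)),
        initial_states=CategoricalDist(np.array([0.5, 0.5])),
        habits=HabitPrior(np.zeros((1, 1))),
        precision_prior=default_precision_prior(),
        policies=[Policy((0,), id=0)],
    )
    link = LevelLink(
        context_map=np.array([0, 1]),
        initial_states=np.array(
            [np.eye(S1)[sidx(0, 0)], np.eye(S1)[sidx(1, 0)]]
        ),
    )
    deep = DeepModel(level1=level1, level2=level2, link=link)
    labels = {
        "task": "context",
        "action_side": {1: "left", 2: "right"},
        "null_actions": [0],
    }
    return deep, ContextChoiceEnvironment(p_cue_valid, labels)


TASKS = {
    "saccade": make_saccade_task,
    "context": make_context_choice_task,
    "repetition": make_repetition_task,
}


def make_task(name: str, seed: int = 0, **kwargs):
    """Build a named task's (model, environment) pair."""
    if name not in TASKS:
        raise ValueError(f"unknown task {name!r}; expected one of {sorted(TASKS)}")
    return TASKS[name](seed=seed, **kwargs)
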