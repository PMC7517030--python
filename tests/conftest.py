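import numpy as np
import pytest

from planinf.model import (
    AgentModel,
    CategoricalDist,
    HabitPrior,
    LikelihoodModel,
    Policy,
    PrecisionBelief,
    PreferenceModel,
    TransitionModel,
    default_precision_prior,
)


@pytest.fixture
def two_state_model():
    """The 2-state, 2-outcome workhorse: likelihood [[0.9, 0.2], [0.1, 0.8]]."""
    A = np.array([[0.9, 0.2], [0.1, 0.8]])
    B = np.stack([np.eye(2), np.array([[0.0, 1.0], [1.0, 0.0]])])
    return AgentModel(
        likelihood=LikelihoodModel(A),
        transitions=TransitionModel(B),
        preferences=PreferenceModel(np.zeros(2)),
        initial_states=CategoricalDist(np.array([0.5, 0.5])),
        habits=HabitPrior(np.zeros((1, 2))),
        precision_prior=default_precision_prior(),
        policies=[Policy((0,), id=0), Policy((1,), id=1)],
    )


@pytest.fixture
def identity_model():
    """Identity likelihood and transitions; uniform everything."""
    A = np.eye(2)
    B = np.eye(2)[None, :, :]
    return AgentModel(
        likelihood=LikelihoodModel(A),
        transitions=TransitionModel(B),
        preferences=PreferenceModel(np.zeros(2)),
        initial_states=CategoricalDist(np.array([0.5, 0.5])),
        habits=HabitPrior(np.zeros((1, 1))),
        precision_prior=default_precision_prior(),
        policies=[Policy((0,), id=0)],
    )


class ScriptedEnvironment:
    """Replays a fixed outcome sequence; for determinism/reduction tests."""

    def __init__(self, script, n_outcomes, labels=None):
        self.script = list(script)
        self.n_outcomes = n_outcomes
        self.labels = labels or {"task": "scripted", "action_side": {}, "null_actions": []}
        self._i = 0

    def reset(self, rng):
        self._i = 1
        return self.script[0]

    def emit(self, action):
        o = self.script[self._i % len(self.script)]
        self._i += 1
        return o


@pytest.fixture
def scripted_env_cls():
    return ScriptedEnvironment
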