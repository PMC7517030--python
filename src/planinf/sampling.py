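"""Seeded random generative models, for property checks and calibration.

These draw fully random (but always valid) categorical models: Dirichlet
likelihood and transition columns, Gaussian preferences, and a random policy
set.  They exist so that algebraic identities (factorisation and
decomposition equivalences, exactness of the marginal likelihood, sign
constraints) can be exercised over a broad family of models rather than a
few hand-picked ones.
"""

from __future__ import annotations

from typing import Optional

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

__all__ = ["random_agent_model", "random_observations"]


def random_agent_model(
    rng: np.random.Generator,
    n_states: Optional[int] = None,
    n_outcomes: Optional[int] = None,
    n_actions: int = 2,
    horizon: int = 2,
    n_policies: Optional[int] = None,
    with_counts: bool = False,
    counts_scale: float = 2.0,
    habit_scale: float = 0.0,
    n_contexts: int = 1,
) -> AgentModel:
    """Draw a random valid agent model (dimensions 2-6 unless given)."""
    S = int(n_states) if n_states else int(rng.integers(2, 7))
    O = int(n_outcomes) if n_outcomes else int(rng.integers(2, 7))
    A = int(n_actions)
    likelihood_matrix = rng.dirichlet(np.ones(O), size=S).T  # (O, S)
    counts = None
    if with_counts:
        counts = rng.gamma(counts_scale, 1.0, size=(O, S)) + 0.1
        likelihood = LikelihoodModel.from_counts(counts)
    else:
        likelihood = LikelihoodModel(likelihood_matrix)
    B = np.stack([rng.dirichlet(np.ones(S), size=S).T for _ in range(A)])
    n_pol = int(n_policies) if n_policies else int(rng.integers(2, 5))
    policies = [
        Policy(tuple(rng.integers(0, A, size=horizon).tolist()), id=i)
        for i in range(n_pol)
    ]
    return AgentModel(
        likelihood=likelihood,
        transitions=TransitionModel(B),
        preferences=PreferenceModel(rng.normal(0.0, 1.0, size=O)),
        initial_states=CategoricalDist(rng.dirichlet(np.ones(S))),
        habits=HabitPrior(habit_scale * rng.normal(size=(n_contexts, n_pol))),
        precision_prior=default_precision_prior(),
        policies=policies,
    )


def random_observations(
    rng: np.random.Generator, model: AgentModel, length: int
) -> list[int]:
    """Sample a valid observation sequence uniformly over outcome indices."""
    return [int(o) for o in rng.integers(0, model.n_outcomes, size=length)]
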