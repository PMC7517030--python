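"""Categorical generative models for discrete planning-as-inference agents.

An :class:`AgentModel` bundles everything one hierarchical level needs:

* a likelihood mapping ``P(o | s)`` (optionally with Dirichlet concentration
  counts so the mapping can be learned),
* action-indexed transition kernels ``P(s' | s, a)``,
* log-preferences over outcomes, ``ln P(o | C)`` up to an additive constant,
* a habit potential ``E(pi, context)`` supplied by a slower timescale,
* a discretised prior over the precision ``beta`` that weights habits against
  the free-energy potentials, and
* a finite set of fixed-length policies (action sequences).

Sign convention used throughout the package: the expected free energy ``G`` is
a quantity to be *maximised* (information gain plus expected log-preference).
Much of the wider literature works with ``-G`` and minimises; be careful when
comparing numbers across implementations.

Array orientation: likelihood arrays are indexed ``[outcome, state]`` with
columns (states) normalised; transition arrays are indexed
``[action, next_state, current_state]`` with columns (current states)
normalised.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PROB_FLOOR",
    "NORM_ATOL",
    "CategoricalDist",
    "LikelihoodModel",
    "TransitionModel",
    "PreferenceModel",
    "HabitPrior",
    "PrecisionBelief",
    "Policy",
    "AgentModel",
    "softmax",
    "log_stable",
    "validate_model",
    "default_precision_prior",
]

#: Probabilities are floored at this value before any logarithm; the equations
#: of the framework assume strictly positive densities.
PROB_FLOOR = 1e-16

#: Tolerance used when checking that distributions sum to one.
NORM_ATOL = 1e-12


def log_stable(p: np.ndarray) -> np.ndarray:
    """Elementwise natural log with probabilities floored at ``PROB_FLOOR``."""
    return np.log(np.maximum(np.asarray(p, dtype=float), PROB_FLOOR))


def softmax(potentials: np.ndarray, axis: int = -1) -> np.ndarray:
    """Exponentiate and normalise a potential vector (stable).

    The maximum is subtracted before exponentiation, so the result is exact up
    to floating point for inputs of any magnitude, and invariant to adding a
    constant to every entry.

    Raises
    ------
    ValueError
        If any entry is NaN or infinite.
    """
    b = np.asarray(potentials, dtype=float)
    if b.size == 0:
        raise ValueError("softmax requires a non-empty argument")
    if not np.all(np.isfinite(b)):
        raise ValueError("softmax argument must be finite")
    z = np.exp(b - b.max(axis=axis, keepdims=True))
    return z / z.sum(axis=axis, keepdims=True)


@dataclass
class CategoricalDist:
    """A normalised distribution over a finite support."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    @classmethod
    def from_unnormalized(cls, w: np.ndarray) -> "CategoricalDist":
        w = np.asarray(w, dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("cannot normalise non-positive weights")
        return cls(w / total)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def violations(self, name: str = "categorical") -> list[str]:
        out = []
        if self.weights.ndim != 1 or self.weights.size < 1:
            out.append(f"{name}: support size must be >= 1")
            return out
        if np.any(self.weights < 0):
            out.append(f"{name}: weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > NORM_ATOL:
            out.append(f"{name}: weights sum to {self.weights.sum():.12g}, not 1")
        return out


@dataclass
class LikelihoodModel:
    """``P(o | s)`` as an outcome x state column-stochastic matrix.

    ``counts`` are optional Dirichlet concentrations over the same support;
    when present the matrix is interpreted as the column-normalised counts and
    learning updates the counts.  ``frozen_mask`` marks entries whose counts
    may not change (the operational reading of an axonal disconnection: the
    efficacy of a cut connection can no longer be modified by experience).
    """

    matrix: np.ndarray
    counts: Optional[np.ndarray] = None
    frozen_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
        if self.frozen_mask is not None:
            self.frozen_mask = np.asarray(self.frozen_mask, dtype=bool)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, frozen_mask: Optional[np.ndarray] = None
    ) -> "LikelihoodModel":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=0, keepdims=True), counts, frozen_mask)

    @property
    def n_outcomes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_states(self) -> int:
        return self.matrix.shape[1]

    def violations(self, name: str = "likelihood") -> list[str]:
        out = []
        if self.matrix.ndim != 2:
            out.append(f"{name}.matrix: must be 2-D (outcome x state)")
            return out
        if np.any(self.matrix < 0):
            out.append(f"{name}.matrix: entries must be nonnegative")
        sums = self.matrix.sum(axis=0)
        for s, total in enumerate(sums):
            if abs(total - 1.0) > NORM_ATOL:
                out.append(
                    f"{name}.matrix: column {s} sums to {total:.12g}, not 1"
                )
        if self.counts is not None:
            if self.counts.shape != self.matrix.shape:
                out.append(f"{name}.counts: shape differs from matrix")
            elif np.any(self.counts <= 0):
                out.append(f"{name}.counts: must be strictly positive")
        if self.frozen_mask is not None:
            ref = self.counts if self.counts is not None else self.matrix
            if self.frozen_mask.shape != ref.shape:
                out.append(f"{name}.frozen_mask: shape differs from counts")
        return out


@dataclass
class TransitionModel:
    """Per-action ``P(s' | s)`` kernels, indexed ``[action, next, current]``."""

    arrays: np.ndarray

    def __post_init__(self) -> None:
        self.arrays = np.asarray(self.arrays, dtype=float)

    @property
    def n_actions(self) -> int:
        return self.arrays.shape[0]

    @property
    def n_states(self) -> int:
        return self.arrays.shape[1]

    def violations(self, name: str = "transitions") -> list[str]:
        out = []
        if self.arrays.ndim != 3 or self.arrays.shape[1] != self.arrays.shape[2]:
            out.append(f"{name}: must be (action, next, current) with square kernels")
            return out
        if np.any(self.arrays < 0):
            out.append(f"{name}: entries must be nonnegative")
        sums = self.arrays.sum(axis=1)
        bad = np.argwhere(np.abs(sums - 1.0) > NORM_ATOL)
        for a, s in bad:
            out.append(
                f"{name}: action {a} column {s} sums to {sums[a, s]:.12g}, not 1"
            )
        return out


@dataclass
class PreferenceModel:
    """Unnormalised log-preferences ``ln P(o | C)`` over outcomes.

    The additive constant is irrelevant (log-probability "plus or minus some
    additive constant" is the utility); the normalised distribution is
    materialised on demand.
    """

    log_pref: np.ndarray

    def __post_init__(self) -> None:
        self.log_pref = np.asarray(self.log_pref, dtype=float)

    def dist(self) -> np.ndarray:
        """The normalised preference distribution P(o | C)."""
        return softmax(self.log_pref)

    def log_dist(self) -> np.ndarray:
        """Normalised log-preferences ln P(o | C)."""
        return log_stable(self.dist())

    def violations(self, name: str = "preferences") -> list[str]:
        if self.log_pref.ndim != 1:
            return [f"{name}: log_pref must be 1-D"]
        if not np.all(np.isfinite(self.log_pref)):
            return [f"{name}: log_pref entries must be finite"]
        return []


@dataclass
class HabitPrior:
    """Context-conditioned habit potentials ``E(pi, context)``.

    Stored as a ``(n_contexts, n_policies)`` real array.  The context axis is
    indexed by states of the level above; a flat (all-zero) habit leaves the
    policy prior entirely to the free-energy potentials.
    """

    potentials: np.ndarray

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)

    @property
    def n_contexts(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_policies(self) -> int:
        return self.potentials.shape[1]

    def violations(self, name: str = "habits") -> list[str]:
        if self.potentials.ndim != 2:
            return [f"{name}: potentials must be 2-D (context x policy)"]
        if not np.all(np.isfinite(self.potentials)):
            return [f"{name}: potentials must be finite"]
        return []


@dataclass
class PrecisionBelief:
    """A distribution over precision (inverse temperature) values ``beta``.

    The support is a finite, strictly increasing grid of positive values, so
    every posterior over beta is exact by enumeration.  ``1 / E[beta]`` is the
    quantity reported as ``precision_inverse`` in logs (the dopamine analogue
    in the neurobiological reading -- a naming convention only).
    """

    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)

    def mean(self) -> float:
        return float(self.grid @ self.weights)

    def copy(self) -> "PrecisionBelief":
        return PrecisionBelief(self.grid.copy(), self.weights.copy())

    def violations(self, name: str = "precision_prior") -> list[str]:
        out = []
        if self.grid.ndim != 1 or self.grid.size < 1:
            out.append(f"{name}: grid must be a non-empty 1-D array")
            return out
        if np.any(self.grid <= 0):
            out.append(f"{name}: grid values must be strictly positive")
        if self.grid.size > 1 and np.any(np.diff(self.grid) <= 0):
            out.append(f"{name}: grid must be strictly increasing")
        if self.weights.shape != self.grid.shape:
            out.append(f"{name}: weights shape differs from grid")
        else:
            if np.any(self.weights < 0):
                out.append(f"{name}: weights must be nonnegative")
            if abs(self.weights.sum() - 1.0) > NORM_ATOL:
                out.append(
                    f"{name}: weights sum to {self.weights.sum():.12g}, not 1"
                )
        return out


@dataclass(frozen=True)
class Policy:
    """A fixed-length sequence of action indices with an integer id."""

    actions: tuple
    id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(int(a) for a in self.actions))

    @property
    def horizon(self) -> int:
        return len(self.actions)


@dataclass
class AgentModel:
    """One hierarchical level's full categorical generative model."""

    likelihood: LikelihoodModel
    transitions: TransitionModel
    preferences: PreferenceModel
    initial_states: CategoricalDist
    habits: HabitPrior
    precision_prior: PrecisionBelief
    policies: list = field(default_factory=list)
    #: per-policy boolean mask set by an expected-free-energy knockout lesion;
    #: None means intact.
    efe_knockout: Optional[np.ndarray] = None

    @property
    def n_states(self) -> int:
        return self.likelihood.n_states

    @property
    def n_outcomes(self) -> int:
        return self.likelihood.n_outcomes

    @property
    def n_actions(self) -> int:
        return self.transitions.n_actions

    @property
    def n_policies(self) -> int:
        return len(self.policies)

    @property
    def horizon(self) -> int:
        return self.policies[0].horizon if self.policies else 0

    def copy(self) -> "AgentModel":
        return _copy.deepcopy(self)


def validate_model(model: AgentModel) -> list[str]:
    """Check every structural invariant; return a list of violations.

    An empty list means the model is well formed.  Each violation names the
    offending field and the invariant it breaks; nothing is raised.
    """
    out: list[str] = []
    out += model.likelihood.violations("likelihood")
    out += model.transitions.violations("transitions")
    out += model.preferences.violations("preferences")
    out += model.initial_states.violations("initial_states")
    out += model.habits.violations("habits")
    out += model.precision_prior.violations("precision_prior")

    S = model.likelihood.n_states
    if model.transitions.arrays.ndim == 3 and model.transitions.n_states != S:
        out.append(
            f"transitions: state dimension {model.transitions.n_states} "
            f"differs from likelihood's {S}"
        )
    if model.preferences.log_pref.ndim == 1 and (
        model.preferences.log_pref.size != model.likelihood.n_outcomes
    ):
        out.append("preferences: length differs from number of outcomes")
    if model.initial_states.weights.ndim == 1 and model.initial_states.n != S:
        out.append("initial_states: length differs from number of states")

    if not model.policies:
        out.append("policies: at least one policy is required")
    else:
        horizons = {p.horizon for p in model.policies}
        if len(horizons) != 1:
            out.append("policies: all policies must share one horizon length")
        A = model.transitions.n_actions
        for p in model.policies:
            if any(a < 0 or a >= A for a in p.actions):
                out.append(f"policies: policy {p.id} uses an invalid action index")
        if model.habits.potentials.ndim == 2 and (
            model.habits.n_policies != len(model.policies)
        ):
            out.append("habits: policy axis differs from number of policies")
    if model.efe_knockout is not None and (
        model.efe_knockout.shape != (len(model.policies),)
    ):
        out.append("efe_knockout: shape differs from number of policies")
    return out


def default_precision_prior(
    n: int = 32,
    lo: float = 0.1,
    hi: float = 10.0,
    shape: float = 4.0,
    rate: float = 4.0,
) -> PrecisionBelief:
    """Gamma(shape, rate) discretised onto a log-spaced beta grid.

    The framework leaves the family of P(beta) open; a Gamma prior on a finite
    grid keeps every precision posterior exact by enumeration while placing
    its mass around beta = shape/rate = 1 by default.
    """
    grid = np.geomspace(lo, hi, n)
    w = stats.gamma.pdf(grid, a=shape, scale=1.0 / rate)
    w = np.maximum(w, PROB_FLOOR)
    return PrecisionBelief(grid, w / w.sum())
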