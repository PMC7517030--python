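"""Load and save agent-model configs (YAML or JSON).

The on-disk format is a flat mapping with the keys ``states``, ``outcomes``,
``actions``, ``likelihood``, ``likelihood_counts``, ``transitions``,
``preferences``, ``initial_states``, ``habits``, ``precision_grid``,
``precision_prior``, ``policies`` (plus the optional ``likelihood_frozen``).
A JSON-Schema document describing it ships in ``planinf/schemas/``.

Round trip: ``load_model(save_model(m))`` reproduces every array bit-exactly
(floats are serialised with full precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .model import (
    AgentModel,
    CategoricalDist,
    HabitPrior,
    LikelihoodModel,
    Policy,
    PrecisionBelief,
    PreferenceModel,
    TransitionModel,
)

__all__ = [
    "ConfigError",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "deep_model_to_dict",
    "deep_model_from_dict",
    "schema_path",
]

REQUIRED_KEYS = (
    "states",
    "outcomes",
    "actions",
    "likelihood",
    "transitions",
    "preferences",
    "initial_states",
    "habits",
    "precision_grid",
    "precision_prior",
    "policies",
)
OPTIONAL_KEYS = ("likelihood_counts", "likelihood_frozen")


class ConfigError(ValueError):
    """A config does not conform to the published schema.

    ``path`` names the offending location, e.g. ``"likelihood[2]"``.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


def schema_path() -> Path:
    """Filesystem path of the JSON-Schema document for model configs."""
    return Path(__file__).parent / "schemas" / "agent_model.schema.json"


def _require_array(cfg: dict, key: str, shape: tuple, dtype=float) -> np.ndarray:
    try:
        arr = np.asarray(cfg[key], dtype=dtype)
    except (TypeError, ValueError) as exc:
        raise ConfigError(key, f"not interpretable as a numeric array ({exc})")
    if arr.shape != shape:
        raise ConfigError(key, f"shape {arr.shape} does not match expected {shape}")
    return arr


def model_from_dict(cfg: dict) -> AgentModel:
    """Build an :class:`AgentModel` from a config mapping."""
    if not isinstance(cfg, dict):
        raise ConfigError("$", "top level must be a mapping")
    for key in REQUIRED_KEYS:
        if key not in cfg:
            raise ConfigError(key, "required key is missing")
    unknown = set(cfg) - set(REQUIRED_KEYS) - set(OPTIONAL_KEYS)
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown key")

    for key in ("states", "outcomes", "actions"):
        if not isinstance(cfg[key], int) or cfg[key] < 1:
            raise ConfigError(key, "must be a positive integer")
    S, O, A = cfg["states"], cfg["outcomes"], cfg["actions"]

    matrix = _require_array(cfg, "likelihood", (O, S))
    counts = None
    if cfg.get("likelihood_counts") is not None:
        counts = _require_array(cfg, "likelihood_counts", (O, S))
    frozen = None
    if cfg.get("likelihood_frozen") is not None:
        frozen = _require_array(cfg, "likelihood_frozen", (O, S), dtype=bool)

    transitions = _require_array(cfg, "transitions", (A, S, S))
    preferences = _require_array(cfg, "preferences", (O,))
    initial = _require_array(cfg, "initial_states", (S,))

    policies_cfg = cfg["policies"]
    if not isinstance(policies_cfg, list) or not policies_cfg:
        raise ConfigError("policies", "must be a non-empty list of action sequences")
    policies = []
    for i, seq in enumerate(policies_cfg):
        if not isinstance(seq, (list, tuple)) or not all(
            isinstance(a, int) for a in seq
        ):
            raise ConfigError(f"policies[{i}]", "must be a list of integer actions")
        policies.append(Policy(tuple(seq), id=i))

    try:
        habits = np.asarray(cfg["habits"], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ConfigError("habits", f"not interpretable as a numeric array ({exc})")
    if habits.ndim != 2 or habits.shape[1] != len(policies):
        raise ConfigError("habits", "must be a 2-D context x policy array")

    grid = np.asarray(cfg["precision_grid"], dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ConfigError("precision_grid", "must be a non-empty 1-D array")
    pweights = _require_array(cfg, "precision_prior", grid.shape)

    return AgentModel(
        likelihood=LikelihoodModel(matrix, counts, frozen),
        transitions=TransitionModel(transitions),
        preferences=PreferenceModel(preferences),
        initial_states=CategoricalDist(initial),
        habits=HabitPrior(habits),
        precision_prior=PrecisionBelief(grid, pweights),
        policies=policies,
    )


def model_to_dict(model: AgentModel) -> dict:
    """Serialise an :class:`AgentModel` to a plain config mapping."""
    cfg: dict[str, Any] = {
        "states": int(model.n_states),
        "outcomes": int(model.n_outcomes),
        "actions": int(model.n_actions),
        "likelihood": model.likelihood.matrix.tolist(),
        "transitions": model.transitions.arrays.tolist(),
        "preferences": model.preferences.log_pref.tolist(),
        "initial_states": model.initial_states.weights.tolist(),
        "habits": model.habits.potentials.tolist(),
        "precision_grid": model.precision_prior.grid.tolist(),
        "precision_prior": model.precision_prior.weights.tolist(),
        "policies": [list(p.actions) for p in model.policies],
    }
    if model.likelihood.counts is not None:
        cfg["likelihood_counts"] = model.likelihood.counts.tolist()
    if model.likelihood.frozen_mask is not None:
        cfg["likelihood_frozen"] = model.likelihood.frozen_mask.astype(bool).tolist()
    return cfg


def deep_model_to_dict(deep) -> dict:
    """Serialise a two-level model: nested level blocks plus a link block."""
    cfg: dict[str, Any] = {
        "level1": model_to_dict(deep.level1),
        "level2": model_to_dict(deep.level2),
        "link": {"context_map": deep.link.context_map.tolist()},
    }
    if deep.link.preferences is not None:
        cfg["link"]["preferences"] = deep.link.preferences.tolist()
    if deep.link.initial_states is not None:
        cfg["link"]["initial_states"] = deep.link.initial_states.tolist()
    return cfg


def deep_model_from_dict(cfg: dict):
    from .hierarchy import DeepModel, LevelLink

    for key in ("level1", "level2", "link"):
        if key not in cfg:
            raise ConfigError(key, "required key is missing")
    link_cfg = cfg["link"]
    if "context_map" not in link_cfg:
        raise ConfigError("link.context_map", "required key is missing")
    link = LevelLink(
        context_map=np.asarray(link_cfg["context_map"], dtype=int),
        preferences=(
            np.asarray(link_cfg["preferences"], dtype=float)
            if link_cfg.get("preferences") is not None
            else None
        ),
        initial_states=(
            np.asarray(link_cfg["initial_states"], dtype=float)
            if link_cfg.get("initial_states") is not None
            else None
        ),
    )
    return DeepModel(
        level1=model_from_dict(cfg["level1"]),
        level2=model_from_dict(cfg["level2"]),
        link=link,
    )


def load_model(source: Union[str, Path]) -> AgentModel:
    """Load a model from a YAML/JSON file path or a config string."""
    text: str
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        cfg = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError("$", f"could not parse config: {exc}")
    return model_from_dict(cfg)


def save_model(model: AgentModel, path: Optional[Union[str, Path]] = None) -> str:
    """Serialise a model to JSON text; optionally write it to ``path``.

    JSON is emitted (valid YAML as well) with full float precision so that a
    load/save round trip is an identity on every array.
    """
    text = json.dumps(model_to_dict(model), indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text
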