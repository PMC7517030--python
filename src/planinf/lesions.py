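"""In-silico lesions and behavioural phenotype statistics.

Three perturbation classes, each the operational reading of a focal insult to
the message passing:

* ``likelihood_disconnection`` -- freeze Dirichlet counts on targeted
  likelihood entries (a cut axon's efficacy can no longer change), abolishing
  their contribution to parameter information gain.  Perception through the
  existing mapping is untouched.  Predicted phenotype: neglect of the frozen
  side of space.
* ``efe_knockout`` -- force G(pi) to zero (the uninformative potential under a
  softmax) for targeted policies from an onset, leaving F and E untouched.
  The posterior is then dominated by the evidence for whatever policy is
  already under way.  Predicted phenotype: perseveration.
* ``precision_clamp`` -- replace the beta grid by a single clamped value.
  Clamped high, the habit dominates and context-inappropriate action is
  suppressed (akinesia); clamped low, the free-energy potentials dominate
  regardless of context (impulsivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .model import AgentModel, PrecisionBelief
from .hierarchy import DeepModel

__all__ = [
    "LesionSpec",
    "PhenotypeSummary",
    "PhenotypeComparison",
    "apply_lesion",
    "summarize_records",
    "phenotype_compare",
]

KINDS = ("likelihood_disconnection", "efe_knockout", "precision_clamp")


@dataclass
class LesionSpec:
    """A perturbation of one of the three kinds.

    ``target_mask`` is a boolean array over likelihood entries
    (likelihood_disconnection) or over policy ids (efe_knockout);
    ``clamp_value`` is the single beta value for precision_clamp.  ``onset``
    is the trial index from which the lesion applies; ``onset_step``
    additionally delays an efe_knockout to a timestep within each affected
    trial (0 = from the start of the trial).
    """

    kind: str
    target_mask: Optional[np.ndarray] = None
    clamp_value: Optional[float] = None
    onset: int = 0
    onset_step: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}; expected one of {KINDS}")
        if self.onset < 0 or self.onset_step < 0:
            raise ValueError("onset and onset_step must be >= 0")
        if self.kind == "precision_clamp":
            if self.clamp_value is None or self.clamp_value <= 0:
                raise ValueError("precision_clamp requires a positive clamp_value")
            if self.target_mask is not None:
                raise ValueError("precision_clamp takes no target_mask")
        else:
            if self.clamp_value is not None:
                raise ValueError(f"{self.kind} takes no clamp_value")
            if self.target_mask is None:
                raise ValueError(f"{self.kind} requires a target_mask")
            self.target_mask = np.asarray(self.target_mask, dtype=bool)


def _lesion_level(model: AgentModel, spec: LesionSpec) -> AgentModel:
    out = model.copy()
    if spec.kind == "likelihood_disconnection":
        if spec.target_mask.shape != out.likelihood.matrix.shape:
            raise ValueError(
                f"target_mask shape {spec.target_mask.shape} does not match "
                f"likelihood shape {out.likelihood.matrix.shape}"
            )
        base = (
            out.likelihood.frozen_mask
            if out.likelihood.frozen_mask is not None
            else np.zeros_like(spec.target_mask)
        )
        out.likelihood.frozen_mask = base | spec.target_mask
    elif spec.kind == "efe_knockout":
        if spec.target_mask.shape != (len(out.policies),):
            raise ValueError(
                f"target_mask length {spec.target_mask.shape} does not match "
                f"{len(out.policies)} policies"
            )
        base = (
            out.efe_knockout
            if out.efe_knockout is not None
            else np.zeros(len(out.policies), dtype=bool)
        )
        out.efe_knockout = base | spec.target_mask
    else:  # precision_clamp
        out.precision_prior = PrecisionBelief(
            np.array([float(spec.clamp_value)]), np.array([1.0])
        )
    return out


def apply_lesion(
    model: Union[AgentModel, DeepModel], spec: LesionSpec
) -> Union[AgentModel, DeepModel]:
    """Return a lesioned copy of a (deep) model; the original is unmodified.

    For a :class:`DeepModel` the lesion targets level 1 (the level that
    perceives and acts).
    """
    if isinstance(model, DeepModel):
        out = model.copy()
        out.level1 = _lesion_level(out.level1, spec)
        return out
    return _lesion_level(model, spec)


@dataclass
class PhenotypeSummary:
    """Operationalised phenotype statistics over a set of trial records.

    * ``laterality_index`` in [-1, 1]: (left - right) saccade proportion.
    * ``repeat_rate`` in [0, 1]: proportion of trials continuing an initiated
      policy past the required count.
    * ``action_rate`` in [0, 1]: proportion of non-null actions.
    """

    laterality_index: float
    repeat_rate: float
    action_rate: float
    counts: dict = field(default_factory=dict)


@dataclass
class PhenotypeComparison:
    intact: PhenotypeSummary
    lesioned: PhenotypeSummary
    #: per-statistic (mean paired difference, bootstrap 2.5%, bootstrap 97.5%)
    differences: dict


def _record_stats(record) -> dict:
    """Per-trial phenotype statistics from one TrialRecord."""
    meta = record.meta
    side = meta.get("action_side", {})  # action index -> "left"/"right"
    null_actions = set(meta.get("null_actions", []))
    n_required = meta.get("n_required")
    repeat_action = meta.get("repeat_action")

    actions = [s.action for s in record.steps if s.action is not None]
    left = sum(1 for a in actions if side.get(a) == "left")
    right = sum(1 for a in actions if side.get(a) == "right")
    lat = (left - right) / (left + right) if (left + right) else 0.0

    n_act = len(actions)
    non_null = sum(1 for a in actions if a not in null_actions)
    action_rate = non_null / n_act if n_act else 0.0

    repeat = 0.0
    if n_required is not None and repeat_action is not None:
        reps = 0
        for a in actions:
            if a == repeat_action:
                reps += 1
            else:
                break
        repeat = 1.0 if reps > n_required else 0.0
    return {
        "laterality_index": lat,
        "repeat_rate": repeat,
        "action_rate": action_rate,
        "left": left,
        "right": right,
        "non_null": non_null,
        "n_actions": n_act,
    }


def summarize_records(records) -> PhenotypeSummary:
    """Aggregate phenotype statistics over trial records."""
    if not records:
        raise ValueError("no records to summarise")
    stats = [_record_stats(r) for r in records]
    left = sum(s["left"] for s in stats)
    right = sum(s["right"] for s in stats)
    n_act = sum(s["n_actions"] for s in stats)
    non_null = sum(s["non_null"] for s in stats)
    return PhenotypeSummary(
        laterality_index=(left - right) / (left + right) if (left + right) else 0.0,
        repeat_rate=float(np.mean([s["repeat_rate"] for s in stats])),
        action_rate=non_null / n_act if n_act else 0.0,
        counts={
            "n_trials": len(records),
            "left_saccades": left,
            "right_saccades": right,
            "actions": n_act,
            "non_null_actions": non_null,
        },
    )


def phenotype_compare(
    intact,
    lesioned,
    n_boot: int = 1000,
    seed: int = 0,
) -> PhenotypeComparison:
    """Paired phenotype comparison with bootstrap percentile intervals.

    Records must come in equal-length, seed-matched lists (record i of each
    condition shares its environment randomness).  For each statistic the
    per-pair differences (lesioned - intact) are resampled ``n_boot`` times
    and the mean difference is reported with its 2.5/97.5 percentile interval.
    """
    if len(intact) != len(lesioned):
        raise ValueError(
            f"record lists differ in length ({len(intact)} vs {len(lesioned)})"
        )
    s_int = [_record_stats(r) for r in intact]
    s_les = [_record_stats(r) for r in lesioned]
    rng = np.random.default_rng(seed)
    n = len(intact)
    differences = {}
    for key in ("laterality_index", "repeat_rate", "action_rate"):
        diffs = np.array([b[key] - a[key] for a, b in zip(s_int, s_les)])
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = diffs[idx].mean(axis=1)
        differences[key] = (
            float(diffs.mean()),
            float(np.percentile(boot_means, 2.5)),
            float(np.percentile(boot_means, 97.5)),
        )
    return PhenotypeComparison(
        intact=summarize_records(intact),
        lesioned=summarize_records(lesioned),
        differences=differences,
    )
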