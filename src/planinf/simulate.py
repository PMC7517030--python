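"""The perception-action loop, structured trial logging, and record I/O.

Per timestep the loop runs the full message-passing cycle:

observe -> exact state inference per policy (F) -> predictive roll-out ->
expected free energy (G, including novelty) -> reciprocal policy/precision
iteration -> action selection -> environment emission -> Dirichlet learning.

Two belief streams coexist deliberately: the per-policy posteriors that score
each *hypothetical* course of action (each policy's own action sequence, the
source of behavioural momentum in F), and a single filtered belief conditioned
on the actions *actually executed*, which is what Dirichlet learning uses for
credit assignment.

Reproducibility: the global seed is expanded into per-trial substreams
(``[seed, trial, 0]`` for the environment, ``[seed, trial, 1]`` for the
agent), so lesioned and intact runs with the same seed share environment
randomness -- the paired design the phenotype comparisons rely on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import AgentModel, CategoricalDist, PreferenceModel, softmax
from .inference import (
    filter_forward,
    posterior_given_policy,
    predict_actions,
    update_dirichlet,
)
from .objectives import expected_free_energy
from .engine import (
    PolicyScores,
    iterate_policy_precision,
    select_action,
)
from .hierarchy import (
    DeepModel,
    ascending_message,
    descending_message,
    level2_update,
)
from .lesions import LesionSpec, apply_lesion, summarize_records

__all__ = [
    "StepRecord",
    "TrialRecord",
    "run_trials",
    "write_records",
    "read_records",
    "records_from_dir",
    "summarize",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "trial",
    "t",
    "observation",
    "action",
    "state_belief",
    "policy_E",
    "policy_F",
    "policy_G",
    "prior_weights",
    "posterior_weights",
    "expected_beta",
    "precision_inverse",
    "iterations",
    "converged",
    "seed",
    "task",
    "lesion",
]


@dataclass
class StepRecord:
    """One timestep of a trial; terminal rows carry the final observation only."""

    t: int
    observation: int
    action: Optional[int]
    state_belief: np.ndarray
    E: Optional[np.ndarray]
    F: Optional[np.ndarray]
    G: Optional[np.ndarray]
    prior_weights: Optional[np.ndarray]
    posterior_weights: Optional[np.ndarray]
    expected_beta: Optional[float]
    precision_inverse: Optional[float]
    iterations: Optional[int]
    converged: Optional[bool]


@dataclass
class TrialRecord:
    """Time-indexed log of one trial."""

    trial: int
    seed: int
    task: str
    lesion: str
    steps: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _env_rng(seed: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(trial), 0])


def _agent_rng(seed: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(trial), 1])


def _knockout_active(model: AgentModel, lesion, trial: int, step: int) -> bool:
    return (
        model.efe_knockout is not None
        and lesion is not None
        and lesion.kind == "efe_knockout"
        and trial >= lesion.onset
        and step >= lesion.onset_step
    )


def run_trials(
    model: Union[AgentModel, DeepModel],
    environment,
    n_trials: int,
    seed: int,
    lesion: Optional[LesionSpec] = None,
    mode: str = "sample",
    learn: bool = True,
    learning_rate: float = 1.0,
    level2_mode: str = "soft",
    task: Optional[str] = None,
    on_trial_end=None,
) -> list[TrialRecord]:
    """Run seeded trials of the perception-action loop; fully reproducible.

    ``lesion`` (if given) is applied from its onset trial; an efe_knockout
    additionally respects ``onset_step`` within each affected trial.  The
    caller's model is never modified.  ``on_trial_end(trial, model)`` (if
    given) is called after each trial with the current working model, e.g. to
    snapshot the learned likelihood.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    is_deep = isinstance(model, DeepModel)
    working = model.copy()
    lesioned = False
    task_id = task or environment.labels.get("task", "custom")
    lesion_id = lesion.kind if lesion is not None else "none"

    level2_belief = working.level2.initial_states.weights.copy() if is_deep else None

    records: list[TrialRecord] = []
    for trial in range(n_trials):
        if lesion is not None and not lesioned and trial >= lesion.onset:
            working = apply_lesion(working, lesion)
            lesioned = True
        level = working.level1 if is_deep else working

        # descending conditioning for this trial
        if is_deep:
            desc = descending_message(level2_belief, working)
            ctx_belief = desc.context_belief
            trial_model = _with_overrides(level, desc.log_pref, desc.initial_states)
        else:
            ctx_belief = np.full(
                level.habits.n_contexts, 1.0 / level.habits.n_contexts
            )
            trial_model = level

        env_rng = _env_rng(seed, trial)
        agent_rng = _agent_rng(seed, trial)
        obs = [int(environment.reset(env_rng))]
        _check_outcome(obs[0], trial_model, trial, 0)
        actions_taken: list[int] = []
        steps: list[StepRecord] = []
        horizon = trial_model.horizon
        policies = trial_model.policies
        n_pol = len(policies)
        loop_result = None

        for t in range(horizon):
            F = np.empty(n_pol)
            G = np.empty(n_pol)
            smoothed_now = np.empty((n_pol, trial_model.n_states))
            for i, pi in enumerate(policies):
                post = posterior_given_policy(trial_model, pi, obs)
                F[i] = post.log_evidence
                smoothed_now[i] = post.smoothed[-1]
                predictive = predict_actions(
                    trial_model, pi.actions[t:], post.filtered[-1]
                )
                G[i] = expected_free_energy(
                    trial_model, predictive, learning_rate=learning_rate
                ).G_total
            if _knockout_active(trial_model, lesion, trial, t):
                G = np.where(trial_model.efe_knockout, 0.0, G)

            scores = PolicyScores(E=trial_model.habits.potentials, F=F, G=G)
            loop_result = iterate_policy_precision(
                scores, trial_model.precision_prior, ctx_belief
            )
            posterior = loop_result.policies
            action = select_action(posterior, policies, t, rng=agent_rng, mode=mode)

            o_new = environment.emit(action)
            try:
                _check_outcome(int(o_new), trial_model, trial, t + 1)
            except ValueError as exc:
                raise RuntimeError(
                    f"environment emitted an invalid outcome at trial {trial}, "
                    f"timestep {t + 1}: {exc}"
                )
            obs.append(int(o_new))
            actions_taken.append(int(action))

            if learn and trial_model.likelihood.counts is not None:
                belief_exec = filter_forward(trial_model, actions_taken, obs)[-1]
                new_lik = update_dirichlet(
                    trial_model.likelihood, obs[-1], belief_exec, rate=learning_rate
                )
                trial_model.likelihood = new_lik
                level.likelihood = new_lik

            w = posterior.weights.weights
            e_beta = loop_result.precision.mean()
            steps.append(
                StepRecord(
                    t=t,
                    observation=obs[t],
                    action=int(action),
                    state_belief=w @ smoothed_now,
                    E=trial_model.habits.potentials.T @ ctx_belief,
                    F=F.copy(),
                    G=G.copy(),
                    prior_weights=softmax(G),
                    posterior_weights=w.copy(),
                    expected_beta=e_beta,
                    precision_inverse=1.0 / e_beta,
                    iterations=loop_result.iterations,
                    converged=loop_result.converged,
                )
            )

        # terminal row: the final observation, no decision
        final_posts = [
            posterior_given_policy(trial_model, pi, obs) for pi in policies
        ]
        F_final = np.array([p.log_evidence for p in final_posts])
        scores = PolicyScores(
            E=trial_model.habits.potentials, F=F_final, G=np.zeros(n_pol)
        )
        final_loop = iterate_policy_precision(
            scores, trial_model.precision_prior, ctx_belief
        )
        w_final = final_loop.policies.weights.weights
        steps.append(
            StepRecord(
                t=horizon,
                observation=obs[horizon],
                action=None,
                state_belief=w_final @ np.stack([p.smoothed[-1] for p in final_posts]),
                E=None,
                F=F_final,
                G=None,
                prior_weights=None,
                posterior_weights=w_final.copy(),
                expected_beta=final_loop.precision.mean(),
                precision_inverse=1.0 / final_loop.precision.mean(),
                iterations=final_loop.iterations,
                converged=final_loop.converged,
            )
        )

        meta = dict(environment.labels)
        if is_deep:
            msg = ascending_message(final_posts, final_loop.policies)
            level2_belief = level2_update(
                working.level2, level2_belief, msg, mode=level2_mode
            )
            meta["level2_belief"] = level2_belief.tolist()
            # propagate the slow state to the next trial
            level2_belief = working.level2.transitions.arrays[0] @ level2_belief
            level2_belief = level2_belief / level2_belief.sum()
        records.append(
            TrialRecord(
                trial=trial,
                seed=seed,
                task=task_id,
                lesion=lesion_id,
                steps=steps,
                meta=meta,
            )
        )
        if on_trial_end is not None:
            on_trial_end(trial, level)
    return records


def _with_overrides(level: AgentModel, log_pref, initial_states) -> AgentModel:
    """Shallow per-trial copy of a level with descending empirical priors."""
    import copy as _copy

    out = _copy.copy(level)
    if log_pref is not None:
        out.preferences = PreferenceModel(np.asarray(log_pref, dtype=float))
    if initial_states is not None:
        out.initial_states = CategoricalDist(np.asarray(initial_states, dtype=float))
    return out


def _check_outcome(o: int, model: AgentModel, trial: int, t: int) -> None:
    if not (0 <= o < model.n_outcomes):
        raise ValueError(
            f"outcome {o} out of range [0, {model.n_outcomes}) "
            f"(trial {trial}, timestep {t})"
        )


def _jarr(x) -> str:
    return json.dumps(np.asarray(x, dtype=float).tolist()) if x is not None else ""


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with the documented column order."""
    if not records:
        raise ValueError("no records to write")
    rows = []
    for rec in records:
        for s in rec.steps:
            rows.append(
                {
                    "trial": rec.trial,
                    "t": s.t,
                    "observation": s.observation,
                    "action": s.action if s.action is not None else -1,
                    "state_belief": _jarr(s.state_belief),
                    "policy_E": _jarr(s.E),
                    "policy_F": _jarr(s.F),
                    "policy_G": _jarr(s.G),
                    "prior_weights": _jarr(s.prior_weights),
                    "posterior_weights": _jarr(s.posterior_weights),
                    "expected_beta": s.expected_beta,
                    "precision_inverse": s.precision_inverse,
                    "iterations": s.iterations,
                    "converged": s.converged,
                    "seed": rec.seed,
                    "task": rec.task,
                    "lesion": rec.lesion,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_records(
    records: list[TrialRecord],
    out_dir: Union[str, Path],
    model_config: Optional[dict] = None,
) -> Path:
    """Write ``trials.csv`` and a ``manifest.json`` run manifest.

    The manifest records the config hash, seed, task, lesion, label metadata,
    and library versions; the CSV uses the fixed ``CSV_COLUMNS`` order with
    full float precision.  An empty record list is an error, not an empty
    file.
    """
    if not records:
        raise ValueError("refusing to write an empty record list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records)
    csv_path = out_dir / "trials.csv"
    try:
        frame.to_csv(csv_path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write {csv_path}: {exc}")

    import scipy

    cfg_text = json.dumps(model_config, sort_keys=True) if model_config else ""
    manifest = {
        "seed": records[0].seed,
        "task": records[0].task,
        "lesion": records[0].lesion,
        "n_trials": len(records),
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "columns": CSV_COLUMNS,
        "labels": {
            k: v for k, v in records[0].meta.items() if k != "level2_belief"
        },
        "versions": {
            "planinf": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return csv_path


def _package_version() -> str:
    from . import __version__

    return __version__


def read_records(csv_path: Union[str, Path]) -> pd.DataFrame:
    """Read ``trials.csv`` back, decoding the JSON-encoded array columns."""
    frame = pd.read_csv(csv_path)
    for col in (
        "state_belief",
        "policy_E",
        "policy_F",
        "policy_G",
        "prior_weights",
        "posterior_weights",
    ):
        frame[col] = frame[col].map(
            lambda v: json.loads(v) if isinstance(v, str) and v else None
        )
    return frame


def records_from_dir(run_dir: Union[str, Path]) -> list[TrialRecord]:
    """Reconstruct lightweight TrialRecords from a written run directory.

    Sufficient for phenotype statistics (actions and labels); belief arrays
    are restored as plain lists.
    """
    run_dir = Path(run_dir)
    frame = read_records(run_dir / "trials.csv")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    labels = manifest.get("labels", {})
    # JSON round-trips dict keys as strings; phenotype lookups use ints
    if "action_side" in labels:
        labels["action_side"] = {int(k): v for k, v in labels["action_side"].items()}
    records = []
    for trial, group in frame.groupby("trial", sort=True):
        steps = [
            StepRecord(
                t=int(row.t),
                observation=int(row.observation),
                action=None if row.action < 0 else int(row.action),
                state_belief=row.state_belief,
                E=row.policy_E,
                F=row.policy_F,
                G=row.policy_G,
                prior_weights=row.prior_weights,
                posterior_weights=row.posterior_weights,
                expected_beta=row.expected_beta,
                precision_inverse=row.precision_inverse,
                iterations=row.iterations,
                converged=row.converged,
            )
            for row in group.itertuples()
        ]
        records.append(
            TrialRecord(
                trial=int(trial),
                seed=int(group["seed"].iloc[0]),
                task=str(group["task"].iloc[0]),
                lesion=str(group["lesion"].iloc[0]),
                steps=steps,
                meta=dict(labels),
            )
        )
    return records


def summarize(records: list[TrialRecord]):
    """Phenotype summary of a record list (delegates to the lesion module)."""
    return summarize_records(records)
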