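"""Seeded synthetic subjects for the stimulus-reward estimation task.

A :class:`GenerativeAgent` carries a probability-estimation model (any entry
of the model zoo), an estimation-noise SD and a softmax temperature for the
lottery-choice block.  :func:`simulate_subject` runs the agent through a full
experiment: outcome sequences are sampled per the design (i.i.d. Bernoulli, or
frequency-matched so realized reward frequencies equal the programmed
probabilities exactly), the agent's model produces a latent estimate from its
own experienced history on every trial, Gaussian noise is added, and the
result is clipped to [0, 1] and discretized onto the design's button scheme.
Lottery choices are sampled from a softmax over the two stimuli's end-of-
session model estimates.  Everything is reproducible from integer seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Union

import numpy as np
import pandas as pd

from .design import (
    ChoiceRecord,
    ExperimentDesign,
    TrialRecord,
    interval_midpoint,
    interval_of,
)
from .models import ModelParams, ModelSpec, final_estimates, predict_series

__all__ = [
    "GenerativeAgent",
    "SubjectDataset",
    "generate_outcomes",
    "simulate_subject",
    "simulate_cohort",
    "subject_to_frames",
    "write_subject_csv",
    "read_subject_csv",
    "write_cohort",
]


@dataclass(frozen=True)
class GenerativeAgent:
    """A simulated subject: model, parameters, noise and choice stochasticity."""

    model_spec: ModelSpec
    params: ModelParams
    noise_sd: float = 0.05
    choice_temperature: float = 10.0
    seed: int = 0
    discretize: bool = True  # report interval midpoints (False: latent values)
    miss_rate: float = 0.0  # probability a trial has no estimate

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be positive")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must lie in [0, 1)")


@dataclass
class SubjectDataset:
    subject_id: str
    design: ExperimentDesign
    trials: List[TrialRecord]
    choices: List[ChoiceRecord] = field(default_factory=list)
    agent_truth: Optional[GenerativeAgent] = None

    def estimates(self, session: Optional[str] = "main") -> pd.DataFrame:
        rows = [
            {
                "session": tr.session,
                "block_index": tr.block_index,
                "trial_index": tr.trial_index,
                "context_id": tr.context_id,
                "stimulus_id": tr.stimulus_id,
                "true_prob": tr.true_prob,
                "outcome": tr.outcome,
                "estimate_interval": tr.estimate_interval,
                "estimate_value": tr.estimate_value,
            }
            for tr in self.trials
            if session is None or tr.session == session
        ]
        return pd.DataFrame(rows)


def _frequency_matched_sequence(p: float, n: int, rng) -> np.ndarray:
    n_rewards = round(p * n)
    if abs(p * n - n_rewards) > 1e-9:
        warnings.warn(
            f"frequency matching infeasible for p={p}, n={n}; "
            f"using nearest-integer reward count {n_rewards}",
            stacklevel=2,
        )
    seq = np.zeros(n, dtype=int)
    seq[:n_rewards] = 1
    rng.shuffle(seq)
    return seq


def generate_outcomes(design: ExperimentDesign, seed: int) -> dict:
    """Per-stimulus outcome sequences, keyed by stimulus id.

    Each value is a dict with ``pre`` and ``main`` binary arrays in that
    stimulus's presentation order.  Frequency-matched designs get exactly
    ``round(p * n)`` rewards over the main session; otherwise outcomes are
    i.i.d. Bernoulli(p).
    """
    rng = np.random.default_rng(seed)
    out = {}
    n_pre = design.pre_trials_per_stimulus
    n_main = design.main_trials_per_stimulus
    for ctx in design.contexts:
        for s, p in zip(ctx.stimulus_ids, ctx.reward_probs):
            pre = (rng.random(n_pre) < p).astype(int)
            if design.frequency_matched:
                main = _frequency_matched_sequence(p, n_main, rng)
            else:
                main = (rng.random(n_main) < p).astype(int)
            out[s] = {"pre": pre, "main": main}
    return out


def _block_plan(design: ExperimentDesign, rng) -> list:
    """Ordered (session, block_index, context, per-stim trial count) tuples."""
    plan = []
    if design.pre_trials_per_stimulus > 0:
        order = rng.permutation(len(design.contexts))
        for b, ci in enumerate(order):
            plan.append(("pre", b, design.contexts[ci], design.pre_trials_per_stimulus))
    reps = [ctx for ctx in design.contexts for _ in range(design.main_blocks_per_context)]
    order = rng.permutation(len(reps))
    for b, ri in enumerate(order):
        plan.append(("main", b, reps[ri], design.main_trials_per_stimulus_per_block))
    return plan


def simulate_subject(
    design: ExperimentDesign,
    agent: GenerativeAgent,
    subject_id: str = "sim_subject",
) -> SubjectDataset:
    """Simulate one subject end to end; fully reproducible from agent.seed."""
    rng = np.random.default_rng(agent.seed)
    outcome_seed = int(rng.integers(2**31))
    outcomes = generate_outcomes(design, outcome_seed)
    cursors = {s: {"pre": 0, "main": 0} for s in design.stimuli}

    trials: List[TrialRecord] = []
    t = 0
    lo_mag, hi_mag = design.reward_magnitudes
    for session, block, ctx, n_per_stim in _block_plan(design, rng):
        order = np.array([0] * n_per_stim + [1] * n_per_stim)
        rng.shuffle(order)
        for which in order:
            s = ctx.stimulus_ids[which]
            k = cursors[s][session]
            outcome = int(outcomes[s][session][k])
            cursors[s][session] = k + 1
            mag = int(rng.integers(lo_mag, hi_mag + 1)) if outcome else 0
            trials.append(
                TrialRecord(
                    session=session,
                    block_index=block,
                    trial_index=t,
                    context_id=ctx.context_id,
                    stimulus_id=s,
                    true_prob=ctx.prob_of(s),
                    outcome=outcome,
                    magnitude=mag,
                )
            )
            t += 1

    dataset = SubjectDataset(subject_id, design, trials, agent_truth=agent)
    _, latent = predict_series(dataset, agent.model_spec, agent.params, include_pre=True)
    noise = rng.normal(0.0, agent.noise_sd, size=len(trials)) if agent.noise_sd > 0 else 0.0
    reported = latent + noise
    if agent.discretize:
        # button responses live on [0, 1]; the continuous diagnostic mode
        # reports the latent value untouched (it may leave [0, 1] when the
        # model's own clipping is disabled)
        reported = np.clip(reported, 0.0, 1.0)
    missing = rng.random(len(trials)) < agent.miss_rate if agent.miss_rate > 0 else np.zeros(len(trials), bool)
    scheme = design.interval_scheme
    for tr, value, miss in zip(trials, reported, missing):
        if miss:
            continue
        if agent.discretize:
            tr.estimate_interval = interval_of(float(value), scheme)
            tr.estimate_value = interval_midpoint(tr.estimate_interval, scheme)
        else:
            tr.estimate_value = float(value)

    dataset.choices = _simulate_choices(dataset, agent, rng)
    return dataset


def _simulate_choices(dataset: SubjectDataset, agent: GenerativeAgent, rng) -> list:
    estimates = final_estimates(dataset, agent.model_spec, agent.params)
    choices = []
    t = 0
    for pair, n in dataset.design.all_lottery_pairs():
        d = estimates[pair[0]] - estimates[pair[1]]
        p_first = 1.0 / (1.0 + np.exp(-agent.choice_temperature * d))
        draws = rng.random(n) < p_first
        for win_first in draws:
            choices.append(ChoiceRecord(pair=pair, chosen=0 if win_first else 1, trial_index=t))
            t += 1
    return choices


ParamSampler = Union[ModelParams, Callable[[np.random.Generator], ModelParams]]


def simulate_cohort(
    design: ExperimentDesign,
    n_subjects: int,
    model_spec: ModelSpec,
    param_sampler: ParamSampler,
    master_seed: int = 0,
    noise_sd: float = 0.05,
    choice_temperature: float = 10.0,
    discretize: bool = True,
    miss_rate: float = 0.0,
) -> List[SubjectDataset]:
    """Independent seeded subjects; ``param_sampler`` may be a point mass
    (a ModelParams) or a callable drawing per-subject parameters."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = param_sampler(rng) if callable(param_sampler) else param_sampler
        agent = GenerativeAgent(
            model_spec=model_spec,
            params=params,
            noise_sd=noise_sd,
            choice_temperature=choice_temperature,
            seed=int(child.generate_state(1)[0] % 2**31),
            discretize=discretize,
            miss_rate=miss_rate,
        )
        cohort.append(simulate_subject(design, agent, subject_id=f"sub-{i:03d}"))
    return cohort


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "session",
    "block_index",
    "trial_index",
    "context_id",
    "stimulus_id",
    "true_prob",
    "outcome",
    "magnitude",
    "estimate_interval",
    "estimate_value",
    "rt",
]
CHOICE_COLUMNS = ["pair_a", "pair_b", "chosen", "trial_index"]


def subject_to_frames(dataset: SubjectDataset):
    trials = pd.DataFrame(
        [
            {
                "session": tr.session,
                "block_index": tr.block_index,
                "trial_index": tr.trial_index,
                "context_id": tr.context_id,
                "stimulus_id": tr.stimulus_id,
                "true_prob": tr.true_prob,
                "outcome": tr.outcome,
                "magnitude": tr.magnitude,
                "estimate_interval": tr.estimate_interval,
                "estimate_value": tr.estimate_value,
                "rt": tr.rt,
            }
            for tr in dataset.trials
        ],
        columns=TRIAL_COLUMNS,
    )
    choices = pd.DataFrame(
        [
            {
                "pair_a": c.pair[0],
                "pair_b": c.pair[1],
                "chosen": c.chosen,
                "trial_index": c.trial_index,
            }
            for c in dataset.choices
        ],
        columns=CHOICE_COLUMNS,
    )
    return trials, choices


def write_subject_csv(dataset: SubjectDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials, choices = subject_to_frames(dataset)
    trials.to_csv(directory / f"{dataset.subject_id}_trials.csv", index=False)
    choices.to_csv(directory / f"{dataset.subject_id}_choices.csv", index=False)


def read_subject_csv(directory, subject_id: str, design: ExperimentDesign) -> SubjectDataset:
    directory = Path(directory)
    trials_df = pd.read_csv(directory / f"{subject_id}_trials.csv")
    trials = []
    for row in trials_df.itertuples(index=False):
        est_i = None if pd.isna(row.estimate_interval) else int(row.estimate_interval)
        est_v = None if pd.isna(row.estimate_value) else float(row.estimate_value)
        rt = None if pd.isna(row.rt) else float(row.rt)
        trials.append(
            TrialRecord(
                session=row.session,
                block_index=int(row.block_index),
                trial_index=int(row.trial_index),
                context_id=int(row.context_id),
                stimulus_id=row.stimulus_id,
                true_prob=float(row.true_prob),
                outcome=int(row.outcome),
                magnitude=int(row.magnitude),
                estimate_interval=est_i,
                estimate_value=est_v,
                rt=rt,
            )
        )
    choices = []
    choice_path = directory / f"{subject_id}_choices.csv"
    if choice_path.exists():
        for row in pd.read_csv(choice_path).itertuples(index=False):
            choices.append(
                ChoiceRecord(
                    pair=(row.pair_a, row.pair_b),
                    chosen=int(row.chosen),
                    trial_index=int(row.trial_index),
                )
            )
    return SubjectDataset(subject_id, design, trials, choices)


def write_cohort(cohort: List[SubjectDataset], directory, master_seed: Optional[int] = None) -> None:
    """Write per-subject CSVs plus a manifest recording seeds and truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"master_seed": master_seed, "subjects": []}
    for ds in cohort:
        write_subject_csv(ds, directory)
        entry = {"subject_id": ds.subject_id, "experiment_id": ds.design.experiment_id}
        if ds.agent_truth is not None:
            entry["seed"] = ds.agent_truth.seed
            entry["noise_sd"] = ds.agent_truth.noise_sd
            entry["model_spec"] = ds.agent_truth.model_spec.to_dict()
            entry["params"] = ds.agent_truth.params.to_dict()
        manifest["subjects"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
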