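"""Experiment designs for the stimulus-reward probability-estimation task.

Six experiments share one layout: three reward probabilities, each assigned to
two distinct visual stimuli, paired into three two-stimulus contexts so that
every probability is experienced under two different contexts.  Subjects report
interval estimates of reward probability on a button scheme that partitions
[0, 1], then perform a post-session binary lottery-choice block.

This module encodes those designs as validated, serializable specifications
plus the interval-discretization helpers used everywhere downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "IntervalScheme",
    "ContextSpec",
    "ExperimentDesign",
    "TrialRecord",
    "ChoiceRecord",
    "EIGHT_BUTTON",
    "TEN_BUTTON",
    "build_design",
    "interval_of",
    "interval_midpoint",
]


@dataclass(frozen=True)
class IntervalScheme:
    """A partition of [0, 1] into response intervals (one per button)."""

    boundaries: tuple

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2:
            raise ValueError("need at least two boundaries")
        if b[0] != 0.0 or b[-1] != 1.0:
            raise ValueError("boundaries must start at 0 and end at 1")
        if any(hi <= lo for lo, hi in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1


#: 8-button scheme of Experiment 1: [0-5], [5-20], ..., [80-95], [95-100] (%).
EIGHT_BUTTON = IntervalScheme((0, 0.05, 0.20, 0.35, 0.50, 0.65, 0.80, 0.95, 1.0))
#: 10-button scheme of Experiments 2-6: ten 10% intervals.
TEN_BUTTON = IntervalScheme(tuple(np.round(np.linspace(0, 1, 11), 10)))


def interval_of(p: float, scheme: IntervalScheme) -> int:
    """1-based index of the interval containing ``p``.

    Intervals are half-open [lo, hi) except the last, which is closed, so
    interval_of(0.50) on the 8-button scheme is 5 (the [50%, 65%] button) and
    interval_of(1.0) is the last interval.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability {p} outside [0, 1]")
    idx = int(np.searchsorted(scheme.boundaries, p, side="right"))
    return min(idx, scheme.n_intervals)


def interval_midpoint(i: int, scheme: IntervalScheme) -> float:
    """Midpoint of the 1-based interval ``i``."""
    if not (1 <= i <= scheme.n_intervals):
        raise ValueError(f"interval index {i} out of range 1..{scheme.n_intervals}")
    return 0.5 * (scheme.boundaries[i - 1] + scheme.boundaries[i])


@dataclass(frozen=True)
class ContextSpec:
    """One block-level context: two stimuli with distinct reward probabilities."""

    context_id: int
    stimulus_ids: tuple
    reward_probs: tuple

    def __post_init__(self):
        if len(self.stimulus_ids) != 2 or len(self.reward_probs) != 2:
            raise ValueError("a context pairs exactly two stimuli")
        if self.stimulus_ids[0] == self.stimulus_ids[1]:
            raise ValueError("stimulus ids within a context must differ")
        if self.reward_probs[0] == self.reward_probs[1]:
            raise ValueError("the two reward probabilities in a context must differ")
        if not all(0 < p < 1 for p in self.reward_probs):
            raise ValueError("reward probabilities must lie in (0, 1)")

    def other_stimulus(self, stimulus_id: str) -> str:
        a, b = self.stimulus_ids
        if stimulus_id == a:
            return b
        if stimulus_id == b:
            return a
        raise KeyError(stimulus_id)

    def prob_of(self, stimulus_id: str) -> float:
        return self.reward_probs[self.stimulus_ids.index(stimulus_id)]


@dataclass(frozen=True)
class ExperimentDesign:
    experiment_id: int
    prob_triplet: tuple
    contexts: tuple  # three ContextSpec
    pre_trials_per_stimulus: int
    main_trials_per_stimulus_per_block: int
    main_blocks_per_context: int
    interval_scheme: IntervalScheme
    reward_magnitudes: tuple  # inclusive integer range, NTD
    frequency_matched: bool
    incentivized: bool
    lottery_trials_same_prob_pair: int = 20
    lottery_trials_other_pair: int = 7

    def __post_init__(self):
        probs = sorted(self.prob_triplet)
        counts = {p: 0 for p in probs}
        stim_ids = []
        for ctx in self.contexts:
            for p in ctx.reward_probs:
                counts[p] += 1
            stim_ids.extend(ctx.stimulus_ids)
        if any(c != 2 for c in counts.values()):
            raise ValueError("each probability must appear in exactly two contexts")
        if len(set(stim_ids)) != 6:
            raise ValueError("the six stimulus ids must be globally distinct")
        if self.main_trials_per_stimulus_per_block <= 0:
            raise ValueError("main trials per stimulus per block must be positive")
        if self.pre_trials_per_stimulus < 0:
            raise ValueError("pre-session trial count cannot be negative")

    # -- convenience lookups -------------------------------------------------
    @property
    def stimuli(self) -> tuple:
        return tuple(s for ctx in self.contexts for s in ctx.stimulus_ids)

    @property
    def main_trials_per_stimulus(self) -> int:
        return self.main_trials_per_stimulus_per_block * self.main_blocks_per_context

    def context_of(self, stimulus_id: str) -> ContextSpec:
        for ctx in self.contexts:
            if stimulus_id in ctx.stimulus_ids:
                return ctx
        raise KeyError(stimulus_id)

    def prob_of(self, stimulus_id: str) -> float:
        return self.context_of(stimulus_id).prob_of(stimulus_id)

    def contexts_with(self, probability: float) -> tuple:
        """The two contexts containing ``probability``, lower-partner first."""
        hits = []
        for ctx in self.contexts:
            for s, p in zip(ctx.stimulus_ids, ctx.reward_probs):
                if math.isclose(p, probability):
                    hits.append((ctx.prob_of(ctx.other_stimulus(s)), ctx, s))
        if len(hits) != 2:
            raise ValueError(f"probability {probability} not in this design")
        hits.sort(key=lambda h: h[0])
        return tuple((ctx, s) for _, ctx, s in hits)

    def same_probability_pairs(self) -> list:
        """The three lottery pairs of same-probability stimuli.

        Each pair is ordered (lower-partner-context stimulus, higher-partner-
        context stimulus), the ordering used for choice probabilities.
        """
        pairs = []
        for p in sorted(self.prob_triplet):
            (c_lo, s_lo), (c_hi, s_hi) = self.contexts_with(p)
            pairs.append((s_lo, s_hi))
        return pairs

    def all_lottery_pairs(self) -> list:
        """All 15 unordered stimulus pairs with their planned trial counts."""
        same = {frozenset(p) for p in self.same_probability_pairs()}
        stimuli = self.stimuli
        pairs = []
        for i in range(len(stimuli)):
            for j in range(i + 1, len(stimuli)):
                pair = (stimuli[i], stimuli[j])
                n = (
                    self.lottery_trials_same_prob_pair
                    if frozenset(pair) in same
                    else self.lottery_trials_other_pair
                )
                pairs.append((pair, n))
        return pairs

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["interval_scheme"] = list(self.interval_scheme.boundaries)
        d["contexts"] = [
            {
                "context_id": c.context_id,
                "stimulus_ids": list(c.stimulus_ids),
                "reward_probs": list(c.reward_probs),
            }
            for c in self.contexts
        ]
        d["prob_triplet"] = list(self.prob_triplet)
        d["reward_magnitudes"] = list(self.reward_magnitudes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["interval_scheme"] = IntervalScheme(tuple(d["interval_scheme"]))
        d["contexts"] = tuple(
            ContextSpec(
                context_id=c["context_id"],
                stimulus_ids=tuple(c["stimulus_ids"]),
                reward_probs=tuple(c["reward_probs"]),
            )
            for c in d["contexts"]
        )
        d["prob_triplet"] = tuple(d["prob_triplet"])
        d["reward_magnitudes"] = tuple(d["reward_magnitudes"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentDesign":
        return cls.from_dict(yaml.safe_load(text))


_TRIPLETS = {
    1: (0.1, 0.5, 0.9),
    2: (0.1, 0.5, 0.9),
    3: (0.1, 0.3, 0.5),
    4: (0.5, 0.7, 0.9),
    5: (0.3, 0.5, 0.7),
    6: (0.1, 0.5, 0.9),
}


def _make_contexts(triplet: Sequence[float]) -> tuple:
    """Pair the sorted triplet (a, b, c) into contexts [a,b], [a,c], [b,c]."""
    a, b, c = sorted(triplet)
    pairs = [(a, b), (a, c), (b, c)]
    contexts = []
    for cid, (lo, hi) in enumerate(pairs, start=1):
        contexts.append(
            ContextSpec(
                context_id=cid,
                stimulus_ids=(f"p{round(lo * 100)}_c{cid}", f"p{round(hi * 100)}_c{cid}"),
                reward_probs=(lo, hi),
            )
        )
    return tuple(contexts)


def build_design(experiment_id: int) -> ExperimentDesign:
    """Fully populated design for one of the six experiments.

    Experiment 1 is the scanner experiment: Bernoulli outcome sampling, the
    8-button scheme, a 3-block pre-session (20 trials/stimulus) and a 6-block
    main session (15 trials/stimulus/block, 2 blocks/context).  Experiments
    2-6 use the 10-button scheme, frequency-matched outcomes and 40 main
    trials per stimulus; 5 and 6 additionally pay an accuracy bonus.
    """
    if experiment_id not in _TRIPLETS:
        raise ValueError(f"unknown experiment_id {experiment_id!r}; expected 1-6")
    triplet = _TRIPLETS[experiment_id]
    if experiment_id == 1:
        return ExperimentDesign(
            experiment_id=1,
            prob_triplet=triplet,
            contexts=_make_contexts(triplet),
            pre_trials_per_stimulus=20,
            main_trials_per_stimulus_per_block=15,
            main_blocks_per_context=2,
            interval_scheme=EIGHT_BUTTON,
            reward_magnitudes=(1, 5),
            frequency_matched=False,
            incentivized=False,
        )
    return ExperimentDesign(
        experiment_id=experiment_id,
        prob_triplet=triplet,
        contexts=_make_contexts(triplet),
        pre_trials_per_stimulus=0,
        main_trials_per_stimulus_per_block=20,
        main_blocks_per_context=2,
        interval_scheme=TEN_BUTTON,
        reward_magnitudes=(1, 5),
        frequency_matched=True,
        incentivized=experiment_id in (5, 6),
    )


@dataclass
class TrialRecord:
    """One stimulus presentation with outcome and (possibly missing) estimate."""

    session: str  # "pre" | "main"
    block_index: int
    trial_index: int  # global presentation order
    context_id: int
    stimulus_id: str
    true_prob: float
    outcome: int
    magnitude: int
    estimate_interval: Optional[int] = None
    estimate_value: Optional[float] = None
    rt: Optional[float] = None

    def __post_init__(self):
        if self.session not in ("pre", "main"):
            raise ValueError("session must be 'pre' or 'main'")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be binary")
        if self.outcome == 0 and self.magnitude != 0:
            raise ValueError("magnitude must be 0 on unrewarded trials")


@dataclass
class ChoiceRecord:
    """One lottery-choice trial over an ordered stimulus pair."""

    pair: tuple
    chosen: int  # 0 or 1, index into pair
    trial_index: int

    def __post_init__(self):
        if self.chosen not in (0, 1):
            raise ValueError("chosen must index into the pair")

    @property
    def chosen_stimulus(self) -> str:
        return self.pair[self.chosen]
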