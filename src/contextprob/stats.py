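"""Behavioral statistics for context effects on probability estimation.

Covers the context-effect deltas (per-probability difference in mean estimate
between the two contexts carrying that probability), the subject-resampling
nonparametric bootstrap test, the trial-level frequency regression
``P_hat(t) = beta_fS * f_S(t; n_past) + beta_foverall * f_overall(t; n_past)``
with its reference-dependency diagnostic ``delta = beta_fS -
(1 - beta_foverall)``, lottery choice probabilities and their model-based
simulation, and the Bonferroni permutation-count rule used for multivoxel
significance testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import ChoiceRecord, ExperimentDesign
from .fitting import BootstrapResult, FitResult
from .models import final_estimates, window_features

__all__ = [
    "RegressionResult",
    "ContextDelta",
    "context_delta",
    "bootstrap_test",
    "fit_frequency_regression",
    "choice_probability",
    "simulate_choice_probability",
    "permutation_count",
]


@dataclass
class ContextDelta:
    """Per-subject context-effect deltas for one reward probability.

    ``per_subject_delta[i]`` is subject i's mean estimate of the probability's
    stimulus in its lower-partner context minus the mean estimate in its
    higher-partner context, so positive values mean the estimate is inflated
    when the companion stimulus carries the smaller reward probability.
    """

    probability: float
    per_subject_delta: np.ndarray
    half: str
    group_mean: float
    subject_ids: tuple = ()


@dataclass
class RegressionResult:
    probability: float
    beta_fS: float
    beta_foverall: float
    n_past: int
    r_squared: float
    delta: float
    n_obs: int


def _half_slice(n: int, half: str) -> slice:
    if half == "all":
        return slice(0, n)
    if half == "first":
        return slice(0, n - n // 2)
    if half == "second":
        return slice(n - n // 2, n)
    raise ValueError(f"unknown half {half!r}")


def context_delta(cohort, probability: float, half: str = "second") -> ContextDelta:
    """Context-induced difference in mean probability estimates.

    For each subject, averages ``estimate_value`` over the requested half of
    the main-session presentations of the probability's stimulus in each of
    its two contexts (per stimulus, in presentation order) and subtracts
    higher-partner from lower-partner context.  Subjects lacking valid trials
    in either context are excluded with a warning.
    """
    deltas, kept = [], []
    for ds in cohort:
        (ctx_lo, s_lo), (ctx_hi, s_hi) = ds.design.contexts_with(probability)
        means = {}
        for s in (s_lo, s_hi):
            vals = [
                tr.estimate_value
                for tr in ds.trials
                if tr.session == "main" and tr.stimulus_id == s
            ]
            vals = [v for v in vals[_half_slice(len(vals), half)] if v is not None]
            means[s] = np.mean(vals) if vals else None
        if means[s_lo] is None or means[s_hi] is None:
            warnings.warn(
                f"{ds.subject_id}: no valid {probability} trials in one context; excluded",
                stacklevel=2,
            )
            continue
        deltas.append(means[s_lo] - means[s_hi])
        kept.append(ds.subject_id)
    arr = np.asarray(deltas, dtype=float)
    return ContextDelta(
        probability=probability,
        per_subject_delta=arr,
        half=half,
        group_mean=float(arr.mean()) if len(arr) else float("nan"),
        subject_ids=tuple(kept),
    )


def bootstrap_test(
    values: Sequence[float],
    null_value: float = 0.0,
    n_boot: int = 10000,
    seed: int = 0,
    stat_name: str = "mean",
) -> BootstrapResult:
    """Nonparametric bootstrap test of the mean of per-subject statistics.

    Resamples subjects with replacement ``n_boot`` times, forms the 95%
    percentile CI of the resampled means, and calls the effect significant
    (alpha = 0.05) when ``null_value`` falls outside the CI.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return BootstrapResult(
        stat_name=stat_name,
        point=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        significant=bool(null_value < lo or null_value > hi),
        null_value=null_value,
    )


def fit_frequency_regression(
    subject,
    probability: float,
    n_past_range: Sequence[int] = range(1, 31),
    intercept: bool = False,
) -> RegressionResult:
    """Trial-level regression of estimates on windowed frequency statistics.

    Pools the main-session estimate trials of the two stimuli carrying
    ``probability`` (one per context), regresses ``estimate_value`` on
    ``f_S(t; n_past)`` and ``f_overall(t; n_past)`` without an intercept,
    scans ``n_past_range`` and keeps the window with the largest R^2
    (uncentered when no intercept is fit).  The reference-dependent account
    predicts ``beta_fS = 1 + tau`` and ``beta_foverall = -tau``, i.e.
    ``delta = beta_fS - (1 - beta_foverall) = 0``.
    """
    design = subject.design
    (ctx_lo, s_lo), (ctx_hi, s_hi) = design.contexts_with(probability)
    target = {s_lo, s_hi}
    best = None
    for n_past in n_past_range:
        f_s, f_os, _ = window_features(subject.trials, design, n_past)
        rows_y, rows_x = [], []
        for i, tr in enumerate(subject.trials):
            if tr.session != "main" or tr.stimulus_id not in target:
                continue
            if tr.estimate_value is None:
                continue
            rows_y.append(tr.estimate_value)
            rows_x.append((f_s[i], 0.5 * (f_s[i] + f_os[i])))
        y = np.asarray(rows_y)
        X = np.asarray(rows_x)
        if len(y) < 3:
            raise ValueError(f"too few estimate trials for probability {probability}")
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError(
                "collinear regressors: f_S and f_overall are linearly dependent "
                f"for probability {probability} at n_past={n_past}"
            )
        design_mat = sm.add_constant(X) if intercept else X
        res = sm.OLS(y, design_mat).fit()
        if best is None or res.rsquared > best[0]:
            best = (res.rsquared, n_past, res.params, len(y))
    r2, n_past, params, n_obs = best
    beta = params[-2:]  # skip intercept if present
    return RegressionResult(
        probability=probability,
        beta_fS=float(beta[0]),
        beta_foverall=float(beta[1]),
        n_past=int(n_past),
        r_squared=float(r2),
        delta=float(beta[0] - (1.0 - beta[1])),
        n_obs=n_obs,
    )


def choice_probability(choices: Sequence[ChoiceRecord], pair) -> float:
    """Fraction of the pair's lottery trials on which ``pair[0]`` was chosen.

    Matches trials regardless of on-screen order, so the probability of a
    pair plus that of its reversal sums to 1.
    """
    want = frozenset(pair)
    n, wins = 0, 0
    for c in choices:
        if frozenset(c.pair) != want:
            continue
        n += 1
        wins += c.chosen_stimulus == pair[0]
    if n == 0:
        raise ValueError(f"no lottery trials for pair {pair}")
    return wins / n


def simulate_choice_probability(
    cohort,
    fits: Dict[str, FitResult],
    seed: int = 0,
    temperature: float = 10.0,
    n_trials_per_pair: Optional[int] = None,
) -> pd.DataFrame:
    """Regenerate same-probability lottery choices from fitted models.

    For every subject, computes end-of-session model estimates under that
    subject's fitted parameters, samples softmax choices for the three
    same-probability pairs, and returns per-subject, per-pair simulated
    choice probabilities (probability of choosing the lower-partner-context
    stimulus).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ds in cohort:
        if ds.subject_id not in fits:
            raise KeyError(f"missing fit for subject {ds.subject_id}")
        fit = fits[ds.subject_id]
        estimates = final_estimates(ds, fit.spec, fit.params_hat)
        n = n_trials_per_pair or ds.design.lottery_trials_same_prob_pair
        for prob, (s_lo, s_hi) in zip(
            sorted(ds.design.prob_triplet), ds.design.same_probability_pairs()
        ):
            d = estimates[s_lo] - estimates[s_hi]
            p_lo = 1.0 / (1.0 + np.exp(-temperature * d))
            cp = float(np.mean(rng.random(n) < p_lo))
            rows.append(
                {
                    "subject_id": ds.subject_id,
                    "probability": prob,
                    "pair": (s_lo, s_hi),
                    "choice_probability": cp,
                    "model_estimate_diff": d,
                }
            )
    return pd.DataFrame(rows)


def permutation_count(n_voxels: int, alpha: float = 0.05) -> int:
    """Permutations prescribed by the Bonferroni rule ``1 / (alpha / n)``."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be at least 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return int(round(n_voxels / alpha))
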