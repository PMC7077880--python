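"""Maximum-likelihood fitting, BIC and bootstrap-BIC model comparison.

The observable is a series of interval probability estimates, modeled as a
Gaussian around the model prediction with a free scale ``sigma_noise``:
``L = prod_i N(est_i | pred_i, sigma_noise^2)``.  Models are compared with
``BIC = ln(n) k - 2 ln(L_max)``, where ``k`` counts the model's free
parameters plus one for ``sigma_noise``.  For group-level comparison the BIC
distribution is reconstructed by resampling subjects with replacement,
recomputing the trial-wise group-average estimate series and refitting.

Group-average series are aligned by ordinal presentation position within each
stimulus-in-context condition: entry j of a condition is the mean (across
subjects, skipping missing responses) of each subject's j-th estimate of that
stimulus.  Model predictions for the group series are each subject's own
predicted series averaged the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (
    ModelParams,
    ModelSpec,
    _PARAM_BOUNDS,
    free_parameter_names,
    predict_core,
    rw_features,
    window_features,
)

__all__ = [
    "FitResult",
    "BootstrapResult",
    "EstimateSeries",
    "gaussian_loglik",
    "compute_bic",
    "fit_model",
    "bootstrap_bic",
    "compare_models",
]


def gaussian_loglik(observed, predicted, noise_sd: float) -> float:
    """Summed log density of the estimates under the Gaussian noise model."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted series must have equal length")
    return float(np.sum(stats.norm.logpdf(observed, loc=predicted, scale=noise_sd)))


def compute_bic(loglik_max: float, k_free: int, n_trials: int) -> float:
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    return float(np.log(n_trials) * k_free - 2.0 * loglik_max)


@dataclass
class FitResult:
    model_name: str
    spec: ModelSpec
    params_hat: ModelParams
    loglik_max: float
    n_trials: int
    k_free: int
    bic: float
    n_past_selected: Optional[int]
    converged: bool
    n_restarts: int
    seed: int
    series_id: str = ""

    def to_dict(self) -> dict:
        d = {
            "model_name": self.model_name,
            "spec": self.spec.to_dict(),
            "params_hat": self.params_hat.to_dict(),
            "loglik_max": self.loglik_max,
            "n_trials": self.n_trials,
            "k_free": self.k_free,
            "bic": self.bic,
            "n_past_selected": self.n_past_selected,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "series_id": self.series_id,
        }
        return d


@dataclass
class BootstrapResult:
    stat_name: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    significant: bool
    null_value: Optional[float] = None
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "stat_name": self.stat_name,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "significant": self.significant,
            "null_value": self.null_value,
            "n_failed": self.n_failed,
        }


class EstimateSeries:
    """An observed estimate series plus the machinery to predict it.

    Holds one or more subject datasets; ``observed`` is either a single
    subject's estimate series or the per-condition ordinal group average.
    ``predict(spec, params)`` produces the matching model series.
    """

    def __init__(self, datasets, session: str = "main", series_id: str = ""):
        if not datasets:
            raise ValueError("need at least one dataset")
        exp_ids = {ds.design.experiment_id for ds in datasets}
        if len(exp_ids) != 1:
            raise ValueError("all datasets must share one experiment design")
        self.datasets = list(datasets)
        self.design = self.datasets[0].design
        self.session = session
        self.series_id = series_id or f"exp{self.design.experiment_id}:{session}:n{len(datasets)}"
        self._feature_cache: Dict[tuple, tuple] = {}

        # group keys: (stimulus, ordinal within session), in design order
        n_per = (
            self.design.pre_trials_per_stimulus
            if session == "pre"
            else self.design.main_trials_per_stimulus
        )
        stimuli = self.design.stimuli
        key_index = {
            (s, j): i for i, (s, j) in enumerate((s, j) for s in stimuli for j in range(n_per))
        }
        self.n_groups = len(key_index)

        self._subject_groups = []  # per subject: (kept positions array, group ids array)
        obs_sum = np.zeros(self.n_groups)
        obs_cnt = np.zeros(self.n_groups)
        for ds in self.datasets:
            ordinals: Dict[str, int] = {}
            kept_pos, group_ids = [], []
            for pos, tr in enumerate(ds.trials):
                if tr.session != session:
                    continue
                j = ordinals.get(tr.stimulus_id, 0)
                ordinals[tr.stimulus_id] = j + 1
                g = key_index[(tr.stimulus_id, j)]
                kept_pos.append(pos)
                group_ids.append(g)
                if tr.estimate_value is not None:
                    obs_sum[g] += tr.estimate_value
                    obs_cnt[g] += 1
            self._subject_groups.append(
                (np.asarray(kept_pos, dtype=int), np.asarray(group_ids, dtype=int))
            )
        self._valid = obs_cnt > 0
        with np.errstate(invalid="ignore"):
            self.observed = (obs_sum / np.where(obs_cnt, obs_cnt, 1))[self._valid]

    def __len__(self) -> int:
        return int(self._valid.sum())

    def _features(self, i: int, spec: ModelSpec, params: ModelParams):
        ds = self.datasets[i]
        if spec.framework == "window":
            key = (i, "window", params.n_past)
            if key not in self._feature_cache:
                f_s, f_os, _ = window_features(ds.trials, ds.design, params.n_past)
                self._feature_cache[key] = (f_s, f_os)
            return self._feature_cache[key]
        f_s, f_os, _ = rw_features(ds.trials, ds.design, params.alpha)
        return f_s, f_os

    def predict(self, spec: ModelSpec, params: ModelParams) -> np.ndarray:
        pred_sum = np.zeros(self.n_groups)
        pred_cnt = np.zeros(self.n_groups)
        for i, (kept_pos, group_ids) in enumerate(self._subject_groups):
            f_s, f_os = self._features(i, spec, params)
            pred = np.atleast_1d(predict_core(spec, params, f_s[kept_pos], f_os[kept_pos]))
            np.add.at(pred_sum, group_ids, pred)
            np.add.at(pred_cnt, group_ids, 1)
        with np.errstate(invalid="ignore"):
            return (pred_sum / np.where(pred_cnt, pred_cnt, 1))[self._valid]

    @classmethod
    def from_subject(cls, dataset, session: str = "main") -> "EstimateSeries":
        return cls([dataset], session=session, series_id=f"{dataset.subject_id}:{session}")

    @classmethod
    def from_cohort(cls, cohort, session: str = "main", series_id: str = "") -> "EstimateSeries":
        return cls(list(cohort), session=session, series_id=series_id)


_SAFE_START = {
    "gamma": (0.3, 2.0),
    "lam": (0.3, 3.0),
    "a": (-0.5, 1.5),
    "b": (0.1, 3.0),
    "alpha": (0.05, 0.95),
}
_PENALTY = 1e12


def _profiled_negloglik(x, names, base_params, spec, series):
    params = base_params.replace(**dict(zip(names, x)))
    try:
        pred = series.predict(spec, params)
    except (ValueError, FloatingPointError):
        return _PENALTY, 0.0
    resid = series.observed - pred
    s2 = float(np.mean(resid**2))
    lo, hi = _PARAM_BOUNDS["noise_sd"]
    sigma = float(np.clip(np.sqrt(max(s2, lo**2)), lo, hi))
    ll = gaussian_loglik(series.observed, pred, sigma)
    if not np.isfinite(ll):
        return _PENALTY, sigma
    return -ll, sigma


def fit_model(
    series: EstimateSeries,
    spec: ModelSpec,
    window_range: Optional[Sequence[int]] = None,
    n_past: int = 30,
    n_restarts: int = 10,
    seed: int = 0,
    model_name: Optional[str] = None,
) -> FitResult:
    """Bounded multi-start maximum-likelihood fit of one model.

    ``sigma_noise`` is profiled out analytically at each evaluation.  With a
    ``window_range``, the model is refit at every window length and the one
    with the largest maximum likelihood is kept (window frameworks only).
    """
    names = list(free_parameter_names(spec))
    bounds = [_PARAM_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)
    if spec.framework == "window" and window_range is not None:
        windows = list(window_range)
    else:
        windows = [n_past if spec.framework == "window" else None]

    best = None  # (negll, sigma, x, window, converged)
    for w in windows:
        base = ModelParams(n_past=w) if w is not None else ModelParams()
        if not names:
            negll, sigma = _profiled_negloglik([], names, base, spec, series)
            cand = (negll, sigma, [], w, negll < _PENALTY)
            if best is None or cand[0] < best[0]:
                best = cand
            continue
        starts = [np.array([np.mean(_SAFE_START[n]) for n in names])]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(np.array([rng.uniform(*_SAFE_START[n]) for n in names]))
        for x0 in starts:
            res = optimize.minimize(
                lambda x: _profiled_negloglik(x, names, base, spec, series)[0],
                x0,
                method="L-BFGS-B",
                bounds=bounds,
            )
            negll, sigma = _profiled_negloglik(res.x, names, base, spec, series)
            cand = (negll, sigma, res.x, w, bool(res.success) and negll < _PENALTY)
            if best is None or cand[0] < best[0]:
                best = cand

    negll, sigma, x, w, converged = best
    params_hat = (ModelParams(n_past=w) if w is not None else ModelParams()).replace(
        **dict(zip(names, np.atleast_1d(np.asarray(x, dtype=float)))), noise_sd=max(sigma, 1e-4)
    )
    loglik_max = -negll
    n_trials = len(series)
    k_free = len(names) + 1  # + sigma_noise
    name = model_name or _registry_name(spec)
    return FitResult(
        model_name=name,
        spec=spec,
        params_hat=params_hat,
        loglik_max=loglik_max,
        n_trials=n_trials,
        k_free=k_free,
        bic=compute_bic(loglik_max, k_free, n_trials),
        n_past_selected=w,
        converged=converged,
        n_restarts=n_restarts,
        seed=seed,
        series_id=series.series_id,
    )


def _registry_name(spec: ModelSpec) -> str:
    from .models import MODEL_REGISTRY

    for name, s in MODEL_REGISTRY.items():
        if (
            s.family == spec.family
            and s.weighted == spec.weighted
            and s.loss_averse == spec.loss_averse
        ):
            return name
    return spec.family


def bootstrap_bic(
    cohort,
    spec: ModelSpec,
    n_boot: int = 10000,
    seed: int = 0,
    n_past: int = 30,
    n_restarts: int = 3,
    session: str = "main",
    model_name: Optional[str] = None,
) -> BootstrapResult:
    """Percentile bootstrap CI of a model's group-average BIC.

    Each resample draws subjects with replacement, recomputes the trial-wise
    group-average estimate series, refits and records the BIC.  Non-convergent
    resamples are excluded and counted.  The window is held fixed at
    ``n_past`` (the full-data choice), not re-selected per resample.
    """
    if len(cohort) < 2:
        raise ValueError("bootstrap requires a cohort of at least 2 subjects")
    rng = np.random.default_rng(seed)
    point_fit = fit_model(
        EstimateSeries.from_cohort(cohort, session=session),
        spec,
        n_past=n_past,
        n_restarts=n_restarts,
        seed=seed,
        model_name=model_name,
    )
    bics = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(cohort), size=len(cohort))
        resample = [cohort[i] for i in idx]
        fit = fit_model(
            EstimateSeries.from_cohort(resample, session=session, series_id="boot"),
            spec,
            n_past=n_past,
            n_restarts=n_restarts,
            seed=int(rng.integers(2**31)),
            model_name=model_name,
        )
        if fit.converged:
            bics.append(fit.bic)
        else:
            n_failed += 1
    if not bics:
        raise RuntimeError("all bootstrap resamples failed to converge")
    lo, hi = np.percentile(bics, [2.5, 97.5])
    return BootstrapResult(
        stat_name=f"BIC[{point_fit.model_name}]",
        point=point_fit.bic,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        significant=False,
        n_failed=n_failed,
    )


def compare_models(
    fits: Sequence[FitResult],
    boots: Optional[Dict[str, BootstrapResult]] = None,
) -> pd.DataFrame:
    """Ascending-BIC ranking with CI-overlap flags.

    When bootstrap CIs are supplied, each pair of models whose 95% CIs overlap
    is flagged as not significantly different.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_set = {f.n_trials for f in fits}
    series_set = {f.series_id for f in fits}
    if len(n_set) > 1 or len(series_set) > 1:
        raise ValueError("fits compare different series definitions")
    boots = boots or {}
    rows = []
    for f in fits:
        b = boots.get(f.model_name)
        rows.append(
            {
                "model": f.model_name,
                "k_free": f.k_free,
                "n_trials": f.n_trials,
                "loglik_max": f.loglik_max,
                "bic": f.bic,
                "ci_low": b.ci_low if b else np.nan,
                "ci_high": b.ci_high if b else np.nan,
            }
        )
    df = pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    overlap_flags = []
    for i, ri in df.iterrows():
        flagged = []
        for j, rj in df.iterrows():
            if i == j or np.isnan(ri.ci_low) or np.isnan(rj.ci_low):
                continue
            if ri.ci_low <= rj.ci_high and rj.ci_low <= ri.ci_high:
                flagged.append(rj.model)
        overlap_flags.append(",".join(flagged))
    df["not_different_from"] = overlap_flags
    return df
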