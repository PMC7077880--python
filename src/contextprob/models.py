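"""Probability-estimation models over experienced reward histories.

Three model classes map recent reward statistics to a probability estimate for
the currently presented stimulus S, whose context partner is OS:

* URD (uncertainty- and reference-dependent):
  ``P = w + tau * (w - f_overall)`` where ``w`` is the (optionally
  gamma-weighted) reward frequency of S, ``f_overall`` is the mean of the two
  per-stimulus frequencies in the context (the reference point), and ``tau``
  is the estimated outcome uncertainty (SD or variance of the binary outcome
  implied by the tracked frequency).  A loss-aversion variant multiplies the
  reference term by ``lam`` when ``w`` falls below the reference.
* DN (divisive normalization), two forms:
  ``(a + f_S) / (b + f_S + f_OS)`` and ``a * f_S / (1 + b * f_overall)``.
* RN (range normalization):
  ``(a + f_S) / (b + max(f_S, f_OS) - min(f_S, f_OS))``.

For DN/RN the optional gamma weighting is applied to the normalized output;
for URD it is applied to ``f_S`` before the reference comparison.  All outputs
are clipped to [0, 1].

The statistics feeding the models evolve under one of two frameworks: a
sliding window that weights the last ``n_past`` presentations of each stimulus
equally, or a Rescorla-Wagner delta rule ``f <- f + alpha * (outcome - f)``
with per-stimulus trackers initialized at 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "FrequencyState",
    "ModelSpec",
    "ModelParams",
    "MODEL_REGISTRY",
    "get_model_spec",
    "free_parameter_names",
    "weight_probability",
    "window_stats",
    "rw_update",
    "predict_urd",
    "predict_dn1",
    "predict_dn2",
    "predict_rn",
    "predict_state",
    "predict_series",
    "window_features",
    "rw_features",
    "final_estimates",
]

PRIOR_FREQUENCY = 0.5  # frequency assumed for a never-seen stimulus


@dataclass(frozen=True)
class FrequencyState:
    """Reward-frequency statistics available when estimating one stimulus."""

    f_S: float
    f_OS: float
    f_overall: float
    sigma_hat: float
    sigma_sq_hat: float
    n_past: Optional[int] = None

    @classmethod
    def from_frequencies(cls, f_S, f_OS, n_past=None) -> "FrequencyState":
        var = f_S * (1.0 - f_S)
        return cls(
            f_S=f_S,
            f_OS=f_OS,
            f_overall=0.5 * (f_S + f_OS),
            sigma_hat=float(np.sqrt(var)),
            sigma_sq_hat=float(var),
            n_past=n_past,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Model family plus variant flags."""

    family: str  # URD | DN1 | DN2 | RN
    weighted: bool = False  # gamma probability weighting
    loss_averse: bool = False  # lambda variant (URD only)
    uncertainty_stat: str = "sd"  # sd | variance | fixed (tau taken from params)
    framework: str = "window"  # window | rescorla_wagner
    clip: bool = True

    def __post_init__(self):
        if self.family not in ("URD", "DN1", "DN2", "RN"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.loss_averse and not (self.family == "URD" and self.weighted):
            raise ValueError("loss aversion is defined only for the weighted URD model")
        if self.uncertainty_stat not in ("sd", "variance", "fixed"):
            raise ValueError(f"unknown uncertainty_stat {self.uncertainty_stat!r}")
        if self.framework not in ("window", "rescorla_wagner"):
            raise ValueError(f"unknown framework {self.framework!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


_PARAM_BOUNDS = {
    "gamma": (0.01, 5.0),
    "lam": (0.01, 10.0),
    "a": (-2.0, 2.0),
    "b": (-2.0, 5.0),
    "alpha": (0.0, 1.0),
    "noise_sd": (1e-4, 1.0),
    "tau": (0.0, 10.0),
}


@dataclass(frozen=True)
class ModelParams:
    """Named parameter values; only those active for a ModelSpec are read."""

    gamma: float = 1.0
    lam: float = 1.0
    a: float = 1.0
    b: float = 0.0
    alpha: float = 0.2
    n_past: int = 30
    noise_sd: float = 0.05
    tau: float = 0.5  # used only when uncertainty_stat == "fixed"

    def __post_init__(self):
        for name, (lo, hi) in _PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"parameter {name}={v} outside bounds [{lo}, {hi}]")
        if not (1 <= self.n_past <= 30):
            raise ValueError("n_past must lie in 1..30")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def free_parameter_names(spec: ModelSpec) -> tuple:
    """Names of a model's free parameters; noise_sd is counted separately."""
    names = []
    if spec.family == "URD":
        if spec.weighted:
            names.append("gamma")
        if spec.loss_averse:
            names.append("lam")
    else:
        names.extend(["a", "b"])
        if spec.weighted:
            names.append("gamma")
    if spec.framework == "rescorla_wagner":
        names.append("alpha")
    return tuple(names)


#: The nine named models of the main analysis.
MODEL_REGISTRY = {
    "URD": ModelSpec("URD"),
    "URD-g": ModelSpec("URD", weighted=True),
    "URD-g-l": ModelSpec("URD", weighted=True, loss_averse=True),
    "DN-1": ModelSpec("DN1"),
    "DN-2": ModelSpec("DN2"),
    "DN-1-g": ModelSpec("DN1", weighted=True),
    "DN-2-g": ModelSpec("DN2", weighted=True),
    "RN": ModelSpec("RN"),
    "RN-g": ModelSpec("RN", weighted=True),
}

_ALIASES = {
    "URD-γ": "URD-g",
    "URD-γ-λ": "URD-g-l",
    "DN-1-γ": "DN-1-g",
    "DN-2-γ": "DN-2-g",
    "RN-γ": "RN-g",
}


def get_model_spec(name: str, framework: str = "window") -> ModelSpec:
    key = _ALIASES.get(name, name)
    if key not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}")
    return replace(MODEL_REGISTRY[key], framework=framework)


# ---------------------------------------------------------------------------
# core expressions (vectorized over numpy arrays)
# ---------------------------------------------------------------------------


def weight_probability(f, gamma: float):
    """One-parameter probability-weighting function.

    ``w = f**g / (f**g + (1-f)**g)**(1/g)``; for 0 < g < 1 small frequencies
    are overweighted and moderate-to-large ones underweighted.  Endpoints 0
    and 1 are fixed for every g > 0.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    num = f**gamma
    den = (f**gamma + (1.0 - f) ** gamma) ** (1.0 / gamma)
    out = num / den
    return out if out.ndim else float(out)


def _tau(spec: ModelSpec, params: ModelParams, f_s):
    if spec.uncertainty_stat == "fixed":
        return params.tau
    var = np.asarray(f_s, dtype=float) * (1.0 - np.asarray(f_s, dtype=float))
    return np.sqrt(var) if spec.uncertainty_stat == "sd" else var


def _maybe_clip(x, spec: ModelSpec):
    return np.clip(x, 0.0, 1.0) if spec.clip else x


def predict_core(spec: ModelSpec, params: ModelParams, f_s, f_os):
    """Model prediction from per-stimulus frequencies (vectorized).

    ``f_overall`` is derived as the unweighted mean of the two frequencies.
    Raises ValueError when a normalization denominator is non-positive.
    """
    f_s = np.asarray(f_s, dtype=float)
    f_os = np.asarray(f_os, dtype=float)
    f_overall = 0.5 * (f_s + f_os)
    if spec.family == "URD":
        w = weight_probability(f_s, params.gamma) if spec.weighted else f_s
        tau = _tau(spec, params, f_s)
        dev = w - f_overall
        term = tau * dev
        if spec.loss_averse:
            term = np.where(dev < 0, params.lam * term, term)
        out = w + term
    else:
        if spec.family == "DN1":
            den = params.b + f_s + f_os
        elif spec.family == "DN2":
            den = 1.0 + params.b * f_overall
        else:  # RN
            den = params.b + np.abs(f_s - f_os)
        if np.any(den <= 0):
            raise ValueError(f"non-positive denominator in {spec.family} model")
        num = params.a * f_s if spec.family == "DN2" else params.a + f_s
        out = num / den
        if spec.weighted:
            out = weight_probability(np.clip(out, 0.0, 1.0), params.gamma)
    out = _maybe_clip(out, spec)
    return out if np.ndim(out) else float(out)


def predict_state(state: FrequencyState, spec: ModelSpec, params: ModelParams) -> float:
    """Prediction from an explicit FrequencyState (uses its own sigma fields)."""
    if spec.family == "URD":
        w = (
            float(weight_probability(state.f_S, params.gamma))
            if spec.weighted
            else state.f_S
        )
        if spec.uncertainty_stat == "fixed":
            tau = params.tau
        elif spec.uncertainty_stat == "sd":
            tau = state.sigma_hat
        else:
            tau = state.sigma_sq_hat
        dev = w - state.f_overall
        term = tau * dev
        if spec.loss_averse and dev < 0:
            term *= params.lam
        return float(_maybe_clip(w + term, spec))
    return float(predict_core(spec, params, state.f_S, state.f_OS))


def predict_urd(state: FrequencyState, spec: ModelSpec, params: ModelParams) -> float:
    if spec.family != "URD":
        raise ValueError("predict_urd requires a URD spec")
    return predict_state(state, spec, params)


def predict_dn1(state: FrequencyState, params: ModelParams, weighted: bool = False) -> float:
    return predict_state(state, ModelSpec("DN1", weighted=weighted), params)


def predict_dn2(state: FrequencyState, params: ModelParams, weighted: bool = False) -> float:
    return predict_state(state, ModelSpec("DN2", weighted=weighted), params)


def predict_rn(state: FrequencyState, params: ModelParams, weighted: bool = False) -> float:
    return predict_state(state, ModelSpec("RN", weighted=weighted), params)


# ---------------------------------------------------------------------------
# state evolution: sliding window
# ---------------------------------------------------------------------------


def window_stats(trials: Sequence, t: int, stimulus_id: str, n_past: int) -> FrequencyState:
    """Frequency statistics for the presentation at global index ``t``.

    Only outcomes of trials strictly before ``t`` enter (the estimate precedes
    that trial's feedback).  ``f_S`` averages the last ``n_past`` presentations
    of ``stimulus_id``; ``f_OS`` does the same for the other stimulus of the
    context; a never-seen stimulus contributes the prior 0.5.
    """
    if not (1 <= n_past <= 30):
        raise ValueError("n_past must lie in 1..30")
    trial = next(tr for tr in trials if tr.trial_index == t)
    if trial.stimulus_id != stimulus_id:
        raise ValueError(f"trial {t} does not present {stimulus_id}")
    past = [tr for tr in trials if tr.trial_index < t]
    own = [tr.outcome for tr in past if tr.stimulus_id == stimulus_id]
    others = {
        tr.stimulus_id for tr in past if tr.context_id == trial.context_id
    } - {stimulus_id}
    # the design guarantees a unique partner; fall back to the prior otherwise
    f_s = float(np.mean(own[-n_past:])) if own else PRIOR_FREQUENCY
    if others:
        os_id = others.pop()
        os_hist = [tr.outcome for tr in past if tr.stimulus_id == os_id]
        f_os = float(np.mean(os_hist[-n_past:])) if os_hist else PRIOR_FREQUENCY
    else:
        f_os = PRIOR_FREQUENCY
    return FrequencyState.from_frequencies(f_s, f_os, n_past=n_past)


# ---------------------------------------------------------------------------
# state evolution: Rescorla-Wagner delta rule
# ---------------------------------------------------------------------------


def rw_update(state: FrequencyState, outcome: int, alpha: float) -> FrequencyState:
    """Delta-rule update of the presented stimulus's tracker."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    f_s = state.f_S + alpha * (outcome - state.f_S)
    return FrequencyState.from_frequencies(f_s, state.f_OS, n_past=state.n_past)


# ---------------------------------------------------------------------------
# per-trial feature tables for whole datasets
# ---------------------------------------------------------------------------


def _presentation_layout(trials):
    """Per-trial (stimulus, #prior own presentations, #prior OS presentations).

    Returns (stim_ids, own_count, os_count, os_id) arrays plus the per-stimulus
    outcome arrays in presentation order.
    """
    outcomes = {}
    counts = {}
    rows = []
    for tr in trials:
        s = tr.stimulus_id
        outcomes.setdefault(s, [])
        counts.setdefault(s, 0)
        rows.append((tr, counts[s]))
        outcomes[s].append(tr.outcome)
        counts[s] += 1
    return rows, {s: np.asarray(v, dtype=float) for s, v in outcomes.items()}


def window_features(trials, design, n_past: int):
    """Arrays (f_S, f_OS, trial_index list) for every trial, sliding window.

    Vectorized via per-stimulus prefix sums; identical to calling
    :func:`window_stats` per trial.
    """
    rows, outcomes = _presentation_layout(trials)
    csums = {s: np.concatenate([[0.0], np.cumsum(v)]) for s, v in outcomes.items()}

    def freq(s, k):  # mean of last min(n_past, k) outcomes before presentation k
        if k == 0:
            return PRIOR_FREQUENCY
        lo = max(0, k - n_past)
        return (csums[s][k] - csums[s][lo]) / (k - lo)

    os_counts = {}
    seen = {}
    f_s = np.empty(len(rows))
    f_os = np.empty(len(rows))
    idx = np.empty(len(rows), dtype=int)
    for i, (tr, k_own) in enumerate(rows):
        ctx = design.context_of(tr.stimulus_id)
        os_id = ctx.other_stimulus(tr.stimulus_id)
        k_os = seen.get(os_id, 0)
        f_s[i] = freq(tr.stimulus_id, k_own)
        f_os[i] = freq(os_id, k_os) if k_os else PRIOR_FREQUENCY
        idx[i] = tr.trial_index
        seen[tr.stimulus_id] = k_own + 1
    return f_s, f_os, idx


def rw_features(trials, design, alpha: float):
    """Arrays (f_S, f_OS, trial_index) under the Rescorla-Wagner tracker.

    Separate tracker per stimulus, initialized at the 0.5 prior and updated
    only on that stimulus's trials, so trackers persist across the two blocks
    of a context and are independent between contexts.
    """
    rows, outcomes = _presentation_layout(trials)
    before = {}
    for s, v in outcomes.items():
        if alpha == 0.0:
            before[s] = np.full(len(v), PRIOR_FREQUENCY)
            continue
        # f_after[k] = (1-a) * f_after[k-1] + a * outcome[k], f_after[-1] = 0.5
        f_after = lfilter([alpha], [1.0, -(1.0 - alpha)], v, zi=[(1.0 - alpha) * PRIOR_FREQUENCY])[0]
        before[s] = np.concatenate([[PRIOR_FREQUENCY], f_after[:-1]])
    # value a tracker holds *after* its k-th update (for the OS lookup)
    after = {
        s: np.concatenate([[PRIOR_FREQUENCY], lfilter([alpha], [1.0, -(1.0 - alpha)], v, zi=[(1.0 - alpha) * PRIOR_FREQUENCY])[0]])
        if alpha > 0.0
        else np.full(len(v) + 1, PRIOR_FREQUENCY)
        for s, v in outcomes.items()
    }
    seen = {}
    f_s = np.empty(len(rows))
    f_os = np.empty(len(rows))
    idx = np.empty(len(rows), dtype=int)
    for i, (tr, k_own) in enumerate(rows):
        ctx = design.context_of(tr.stimulus_id)
        os_id = ctx.other_stimulus(tr.stimulus_id)
        k_os = seen.get(os_id, 0)
        f_s[i] = before[tr.stimulus_id][k_own]
        f_os[i] = after[os_id][k_os]
        idx[i] = tr.trial_index
        seen[tr.stimulus_id] = k_own + 1
    return f_s, f_os, idx


def predict_series(dataset, spec: ModelSpec, params: ModelParams, include_pre: bool = True):
    """Model predictions for every trial of a subject dataset.

    Returns (trial_index array, prediction array) in presentation order.  The
    history always accumulates across the pre and main sessions; with
    ``include_pre=False`` predictions are returned for main-session trials
    only (their statistics still see the pre-session history).
    """
    trials = dataset.trials
    if spec.framework == "window":
        f_s, f_os, idx = window_features(trials, dataset.design, params.n_past)
    else:
        f_s, f_os, idx = rw_features(trials, dataset.design, params.alpha)
    pred = predict_core(spec, params, f_s, f_os)
    pred = np.atleast_1d(pred)
    if not include_pre:
        keep = np.asarray([tr.session == "main" for tr in trials])
        return idx[keep], pred[keep]
    return idx, pred


def final_estimates(dataset, spec: ModelSpec, params: ModelParams) -> dict:
    """End-of-session model estimate per stimulus (all outcomes observed)."""
    _, outcomes = _presentation_layout(dataset.trials)
    design = dataset.design
    freqs = {}
    for s, v in outcomes.items():
        if spec.framework == "window":
            freqs[s] = float(np.mean(v[-params.n_past:])) if len(v) else PRIOR_FREQUENCY
        else:
            a = params.alpha
            f = PRIOR_FREQUENCY
            for o in v:
                f += a * (o - f)
            freqs[s] = f
    out = {}
    for s in design.stimuli:
        os_id = design.context_of(s).other_stimulus(s)
        out[s] = float(
            predict_core(spec, params, freqs.get(s, PRIOR_FREQUENCY), freqs.get(os_id, PRIOR_FREQUENCY))
        )
    return out
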