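# Methods

## Task designs

Six experiment designs are built in (`build_design(1..6)`). Each uses three
reward probabilities, every probability assigned to two distinct visual
stimuli, and the six stimuli paired into three two-stimulus contexts so each
probability is experienced under two contexts differing only in the partner's
probability. Experiment 1 (the scanner design) uses probabilities
10/50/90%, a 3-block pre-session (40 trials per block, 20 per stimulus), a
6-block main session (30 trials per block, 15 per stimulus, 2 blocks per
context), i.i.d. Bernoulli outcome sampling, reward magnitudes 1–5 NTD
drawn uniformly on rewarded trials, and an 8-button interval scheme with
boundaries at 0, 5, 20, 35, 50, 65, 80, 95, 100%. Experiments 2–6 use a
10-button scheme of equal 10% intervals, 40 main trials per stimulus
(2 blocks per context of 20), and frequency matching: each stimulus's
realized main-session reward count equals `round(p · n)` exactly, removing
between-subject sampling variability in experienced frequencies.
Probability triplets are 10/50/90 (Experiments 2 and 6), 10/30/50 (3),
50/70/90 (4) and 30/50/70 (5); Experiments 5 and 6 flag accuracy
incentivization (which does not change the generative dynamics here).
Block order is randomized per subject; stimulus order is randomized within
block. Every design serializes to YAML for user-defined variants.

Two conventions the estimates rest on:

* **Interval boundaries** are half-open `[lo, hi)` with the last interval
  closed, so a response of exactly 0.50 on the 8-button scheme falls in the
  [50%, 65%] button. The schemes only print abutting interval labels, so a
  convention had to be fixed; half-open-from-below makes `interval_of`
  total and keeps `interval_of ∘ interval_midpoint` the identity.
* **Numeric value of an interval response** is the interval midpoint. Under
  a uniform within-interval prior the midpoint is the unbiased choice; the
  mapping is localized in `interval_midpoint` and therefore pluggable. The
  lottery design uses the corrected trial counts throughout (20 trials per
  same-probability pair, 7 per remaining pair, 144 total).

## Models

All models map per-stimulus reward-frequency statistics to a probability
estimate, clipped to [0, 1] after the full expression:

* **URD**: `P = w + τ(w − f_overall)` with `w` the γ-weighted frequency for
  the weighted variant (weighting applied to `f_S` *before* the reference
  comparison) and `τ` the estimated outcome uncertainty. We use the
  population Bernoulli statistics implied by the tracked frequency,
  `σ̂² = f_S(1 − f_S)`, rather than a small-sample variance: it is smooth,
  parameter-free and defined from the first trial. The `uncertainty_stat`
  switch selects `τ = σ̂` or `τ = σ̂²`; a third setting, `fixed`, holds τ
  constant and exists for diagnostics (it makes the model exactly linear in
  `(f_S, f_overall)`). The loss-averse variant multiplies the reference term
  by λ > 0 only when `w − f_overall < 0`.
* **DN-1** `(a + f_S)/(b + f_S + f_OS)`, **DN-2** `a·f_S/(1 + b·f_overall)`,
  **RN** `(a + f_S)/(b + |f_S − f_OS|)`. The optional γ weighting is applied
  to the normalized output (clipped to [0, 1] first, since the weighting
  function's domain is the unit interval). Non-positive denominators raise;
  during optimization they are treated as an infinite-deviance penalty.

The γ weighting is the one-parameter form
`w = f^γ/(f^γ + (1−f)^γ)^(1/γ)`. A known property of this form is
non-monotonicity for γ below ≈ 0.279; the optimizer bound (γ ≥ 0.01) admits
that region, so fits with very small γ̂ should be inspected.

**Statistic evolution.** The window framework computes `f_S` over the last
`n_past ∈ 1..30` presentations *of each stimulus* (not the last `n_past`
trials overall), `f_OS` likewise for the context partner, and
`f_overall = (f_S + f_OS)/2`. Statistics for trial *t* use outcomes up to
trial *t − 1* only — the estimate precedes that trial's feedback. Histories
shorter than the window use all available trials; a never-seen stimulus
contributes a prior of 0.5. Pre- and main-session histories are pooled by
default (`include_pre` controls which trials are *predicted*, not which feed
the statistics). The Rescorla–Wagner framework keeps one tracker per
stimulus, initialized at 0.5, updated as `f ← f + α(o − f)` with a single
shared learning rate per model; trackers persist across the two blocks of a
context and are independent between contexts. The update is implemented as
a first-order linear filter, so likelihood evaluations are vectorized.

## Synthetic cohorts

`simulate_subject` composes the pieces: seeded outcome sequences, latent
model estimates from the agent's own experienced history, additive Gaussian
response noise (`noise_sd`), clipping to [0, 1], and discretization onto the
design's button scheme. Lottery choices are sampled from a softmax over the
two stimuli's end-of-session model estimates with inverse temperature 10 by
default — on a 0–1 estimate scale this makes a 0.1 estimate gap a ~73/27
preference, a realistic stochastic-choice level; the "final estimate" is the
model prediction after each stimulus's last main-session trial. An optional
miss rate reproduces missing-response handling. Cohorts derive independent
per-subject seeds from a master seed via `SeedSequence`, and the generating
agent is retained on each dataset for recovery studies.

The default study conditions used by the seeded cohort tests are the
scanner design with 34 subjects, a weighted-URD agent with γ = 0.6 (typical
probability-weighting curvature), a 10-trial window (the reward-history
horizon that also drives the package's short-horizon regressors),
`noise_sd = 0.05`, and **variance-weighted uncertainty** (`τ = σ̂²`). The
variance form is deliberate: with SD weighting the model predicts context
effects at 10%/90% of roughly `E[σ̂]·0.2 ≈ 0.05`, large enough to be
reliably significant at n = 34 under low response noise — whereas human
estimates show no reliable effect at the extremes. Since `σ̂² ≤ σ̂` for
binary outcomes, variance weighting damps exactly the extreme-probability
effects while preserving the strong 50% effect, reproducing the empirical
pattern (significant Δ₅₀, null Δ₁₀/Δ₉₀, and the matching lottery-choice
ordering). This is a statement about which generative agent emulates human
behavior, not about which fits it best — model comparison is run separately.

What the generator does *not* emulate: response times, attention lapses
beyond the uniform miss rate, subject-level idiosyncrasies other than
parameter heterogeneity (a `param_sampler` can draw per-subject parameters),
sequential response biases (anchoring on the previous button), and any
within-session drift in strategy. Passing tests therefore certify the
pipeline's statistical machinery and the models' qualitative signatures,
not that human data will match any particular parameter set.

## Fitting

The likelihood treats each estimate as Gaussian around the model prediction
with free scale `σ_noise`; missing responses are excluded. `σ_noise` is
profiled analytically (its conditional MLE is the residual RMS, clipped to
[1e-4, 1]), which removes one search dimension; it still counts as a free
parameter in `k` for BIC. Remaining parameters are optimized by L-BFGS-B
with 10 seeded random restarts inside bounds γ ∈ [0.01, 5], λ ∈ [0.01, 10],
a ∈ [−2, 2], b ∈ [−2, 5], α ∈ [0, 1]; restarts start inside a conservative
sub-box to avoid the invalid-denominator region. The plain URD model has no
searchable parameters, so its "fit" is a single profiled evaluation. When a
window range is supplied, the model is refit at every window length and the
largest maximum likelihood wins; ties break toward the shorter window.

Group-average fitting aligns trials by ordinal presentation position within
each stimulus-in-context condition, averaging observed estimates across
subjects (skipping missing values) and averaging the per-subject model
predictions the same way. Bootstrap-BIC resamples subjects with
replacement, rebuilds the group series, refits (3 restarts per resample) and
returns the 95% percentile interval; the window is held at the full-data
selection rather than re-selected per resample, trading a small optimism for
a large speedup. Non-convergent resamples are excluded and counted.
`compare_models` ranks fits by BIC and flags pairs whose bootstrap CIs
overlap as not significantly different.

## Behavioral statistics

* `context_delta`: per subject, mean estimate of a probability's stimulus in
  its lower-partner context minus its higher-partner context (positive =
  inflation beside the weaker partner), over the chosen half of each
  stimulus's main-session presentations. "Second half" splits per stimulus,
  since contexts are interleaved at the block level.
* `bootstrap_test`: subject-level resampling (default 10,000 resamples),
  95% percentile CI, significance = null outside the CI. Calibration under
  a Gaussian null at n = 34 is ~5% type-I error (checked at 1,000
  replications, 2,000 resamples each).
* `fit_frequency_regression`: trial-level no-intercept least squares of
  estimates on `f_S(t; n_past)` and `f_overall(t; n_past)` over the two
  stimuli sharing a probability, scanning windows 1–30 and keeping the best
  R² (uncentered, as appropriate without an intercept; an intercept flag
  exists but defaults off). Under the linear reference rule with fixed
  susceptibility τ this recovers `β_fS = 1 + τ`, `β_foverall = −τ` exactly,
  i.e. the diagnostic `Δ = β_fS − (1 − β_foverall)` is 0. Exactly collinear
  regressors (e.g. deterministic equal histories) raise a collinearity
  error rather than returning an arbitrary solution.
* `choice_probability` matches pairs irrespective of presentation order, so
  a pair and its reversal sum to 1; `simulate_choice_probability` regenerates
  the three same-probability pairs' choices from each subject's fitted model
  (softmax over end-of-session estimates), mirroring the model-based choice
  analysis.
* `permutation_count(n, α) = round(n/α)` is the Bonferroni permutation rule
  used for multivoxel ROI testing, kept as a standalone utility.

## Problem sizes in the test suite

The stochastic studies are sized to run on one CPU in a few minutes, as the
package's own scaling choices: model recovery uses 20 cohorts of 12 subjects
with the window fixed at the generating length and 5 optimizer restarts;
parameter recovery uses 12 subjects of the frequency-matched design;
bootstrap calibration uses 1,000 replications of 2,000 resamples;
bootstrap-BIC checks use 50 resamples. The same code paths accept the
full-scale settings (10,000 resamples, window scans) unchanged.

## Known limitations

* The Rescorla–Wagner variant is a standard single-learning-rate
  reconstruction (per-stimulus trackers initialized at 0.5); richer
  parameterizations (separate rates per statistic, free initial values) are
  not implemented.
* Range normalization with a near-zero fitted `b` is numerically fragile
  when the two context frequencies coincide; the positive-denominator guard
  turns such regions into penalties, which can make RN-γ fits sensitive to
  restarts.
* The group-average predictor averages per-subject predictions; if subjects
  have heterogeneous windows this is an approximation to fitting each
  subject separately.
* Only the nine named models of the main comparison are registered;
  supplementary variants (partner-frequency reference, doubly-weighted
  forms, free uncertainty gains) are out of scope, though `uncertainty_stat`
  covers the variance-weighted variant.
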