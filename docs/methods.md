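# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `mibci`, and what the synthetic benchmarks do and do not
demonstrate.

## Signal model and preprocessing

Recordings are 16-channel scalp EEG over the sensorimotor strip (FC3…Pz,
10/20 convention) sampled at 250 Hz, in microvolts. Preprocessing is
linear and applied to the **continuous** recording, before epoching, so no
filter startup transient lands inside an analysis window:

* **Band-pass**: 4th-order Butterworth, 8–30 Hz. This covers the mu
  (8–13 Hz) and beta (13–30 Hz) bands where imagery-related power changes
  live, and removes drift and most EMG.
* **Notch**: 3rd-order Butterworth band-stop, ±2 Hz around each of 50 and
  60 Hz, cascaded. With an 8–30 Hz pass-band the notch is nearly
  redundant; it is retained because the acquisition convention applies it.
  The band-stop half-width (2 Hz) is this package's choice; the filter
  "order 3, notch type" names no bandwidth by itself.
* **Reference (CAR)**: subtract the instantaneous mean over all 16
  channels from every channel. CAR is idempotent and annihilates any
  common-mode component; it also makes the channel-sum direction exactly
  zero-variance, which the CSP stage must handle (below).

All filters run **zero-phase** (forward–backward, `sosfiltfilt`). This is
an offline-analysis contract: it preserves ERD latency alignment at the
cost of acausality. The effective magnitude response is the square of the
single-pass Butterworth response, which is exactly what the filter oracles
in the test suite assert.

## Trials and windows

A trial spans [−2, +7) s around the MI cue: 2 s pre-cue baseline, 5 s
imagery, 2 s post interval (2250 samples at 250 Hz). Epochs use half-open
0-based sample intervals; trials containing non-finite samples are dropped
with a warning. Analysis windows of length T (2 or 3 s) slide in 0.2-s
steps; the grid is computed in **integer samples** (0.2 s = exactly 50
samples at 250 Hz), so window positions carry no floating-point drift and
the T = 2 s grid has exactly 36 positions (−2.0, −1.8, …, +5.0 s).

## CSP and features

For each window position, per-trial spatial covariances are computed over
time (channel means removed), **trace-normalized** (so every trial
contributes equal power), and averaged within class to give C_L and C_R.
CSP solves the simultaneous-diagonalization problem by whitening with the
composite C_L + C_R and eigendecomposing the whitened C_L; rows of the
resulting W are spatial filters with W C_L Wᵀ = diag(λ),
W C_R Wᵀ = diag(1 − λ), λ sorted descending. Patterns (for topographic
maps) are the columns of W⁻¹. The first and last m = 2 filters are
retained; each windowed trial then yields four features
f_r = log(VAR_r / Σ VAR), whose exponentials sum to one by construction
and which are invariant to trial-wise amplitude scaling.

Numerical choices:

* **Ridge**: a ridge of 1e−10 × (mean channel variance), split equally
  between C_L and C_R, is added before whitening, escalating to 1e−8 and
  1e−4 (with a warning) if the composite remains ill-conditioned.
  Splitting the ridge between the class matrices rather than adding it to
  the composite is deliberate: a direction with zero variance in both
  classes — the channel sum, after CAR — then receives a whitened
  eigenvalue of exactly ½ and sorts to the *middle* of the spectrum, where
  it is never selected. Adding the ridge to the composite alone parks
  that direction at eigenvalue 0, i.e. at the top of the "other class"
  ranking, where it would be selected and produce log(0) features. The
  magnitude 1e−10 dominates the float-level noise of the CAR null
  direction (~1e−16 relative) by six orders while perturbing the
  eigenvalue-pairing identity λ_L + λ_R = 1 by well under 1e−8.
* The same relative ridge is added to per-trial covariances when features
  are computed, keeping a null-direction filter's variance finite and
  uninformative; the perturbation of well-conditioned components is
  O(1e−10) and scale-invariance is preserved exactly.
* **Sign convention**: each filter is scaled so its largest-magnitude
  pattern entry is positive (reproducible plots and tests). Eigenvalue
  ties keep the eigendecomposition's order; the choice is non-semantic.
* Features are computed as quadratic forms on per-trial covariances
  (VAR_r = w_r C w_rᵀ), which is algebraically identical to projecting
  the time series and taking temporal variances; a test asserts the two
  routes agree to 1e−12. The covariance route lets cross-validation,
  permutation nulls and transfer evaluation reuse one covariance tensor
  per window instead of re-projecting time series per fold.

## Classification and the session statistic

* **LDA**: two-class Fisher discriminant with pooled within-class
  covariance (ridge 1e−9 × trace), equal priors; the boundary passes
  through the class-mean midpoint.
* **SVM**: soft-margin, cost C = 1, on features standardized with
  training-partition mean/SD. Linear kernel, or the inhomogeneous cubic
  kernel (γ⟨x, x′⟩ + 1)³ with γ = 1/4 (one over the feature count).
  Hyperparameters are recorded in every results manifest.
* **Cross-validation**: stratified 10-fold. The fold assignment is drawn
  once per epoch set from the classifier seed and reused across all window
  positions, so the max-over-windows statistic is not inflated by
  per-window refold variance. CSP, feature extraction and feature
  standardization are fitted inside each training partition only; an
  instrumentation test verifies that corrupting a held-out fold leaves
  that fold's training features bit-identical.
* **Session accuracy** = max over window positions of the fold-mean
  accuracy, ties broken toward the earliest window. Note this max is an
  optimistically biased statistic by construction — on a no-signal session
  it sits well above 50% (typically 60–70% over 36 windows) — which is
  why the package also provides the matching **max-statistic permutation
  null** (`permutation_null`): labels are permuted, the full curve is
  recomputed, and its maximum is retained, giving the correct reference
  distribution for the session accuracy.
* **Transfer evaluation** (`run_train_test`): CSP + classifier fitted once
  per window on a full calibration run, scored on held-out runs, matching
  the calibrate-then-test protocol of multi-run sessions.
* Reported percentages are rounded half-up to 2 decimals.

Chance level is 50% (balanced two-class); the 60% "good performance"
threshold is a report flag, not a computation.

## ERD/ERS maps

Per channel, class and frequency (default 8–30 Hz in 2-Hz steps): filter
the epochs in a 2-Hz band centered on f (zero-phase, with ~3 s of reflect
padding — the narrowband ring-down far exceeds `sosfiltfilt`'s default
padding), square, average over the class's trials, smooth with a 250-ms
moving average, and express as percent change relative to the mean power
over the [−2, 0) s pre-cue baseline. Negative values are ERD. The
formula is the classical band-power ratio; filtering per epoch leaves
residual edge transients in roughly the first/last second of the 9-s
trial, so quantitative summaries should stay inside the interior (the
tests use [0.5, 4.5] s for the imagery interval).

## The synthetic-session generator

`simulate_session` emulates the acquisition protocol: 40 trials per class
(80 per session) in seeded-shuffle order, 9-s trial structure with cue at
t = 0, uniform 2–3 s inter-trial gaps, 250 Hz, 16 channels. The signal
model is x(t) = M s(t) + pink noise + line noise:

* **Sources**: two unit-variance narrowband Gaussian processes (white
  noise band-passed ±1 Hz around 10 Hz) plus a weaker beta component
  (amplitude 0.4, around 20 Hz), located at the C3 and C4 coordinates.
* **Mixing** M: Gaussian-distance kernel over the montage,
  exp(−d²/2ℓ²) with length scale ℓ = 0.3 head-circle units — a smooth
  stand-in for volume conduction, not a head model.
* **ERD**: during the [0, 5] s imagery interval the source contralateral
  to the imagined hand is amplitude-scaled by (1 − depth), with 200-ms
  raised-cosine ramps at the interval edges so the gating itself adds no
  broadband transient (power therefore drops to (1 − depth)² of baseline,
  which the tests verify on the pre-mixing source). The ipsilateral
  source is unmodulated by default; an optional ERS gain exists. Default
  depth 0.7 and SNR 2 (source power over pink-noise power at the nearest
  channel) put session accuracies in the range the best-performing real
  subjects reach; no quantitative ERD magnitude is established for this
  kind of recording, so the depth is an explicit free parameter and the
  benchmarks sweep it.
* **Noise**: per-channel 1/f-power (pink) noise, RMS 10 µV, mimicking the
  EEG spectrum; a 1 µV 50 Hz sinusoid (common phase across channels)
  exercises the notch stage.
* Everything is reproducible from the config seed; multi-run sessions
  derive per-run sub-seeds by seed-sequence spawning.

What the generator does **not** model: realistic volume conduction, ocular
and muscular artifacts, non-stationary background rhythms, inter-subject
variability in source location, or feedback effects. Passing the
parameter-recovery benchmarks therefore certifies that the pipeline
recovers planted contralateral ERD of known depth under pink noise — it
does not certify performance on real recordings, whose accuracies depend
on data that are not distributable with this package. The group-statistics
stage, by contrast, runs on the study's actual tabulated per-subject
accuracies and reproduces the published p-value columns exactly.

## Paired statistics

* **Exact Wilcoxon signed-rank** (two-sided): ranks of |y − x| with
  average ranks for ties, zero differences dropped with a warning,
  W = min(W⁺, W⁻), and p = 2 P(W_null ≤ W) under the enumeration of all
  2ⁿ sign assignments. The null distribution is built by shift
  convolution in exact integer arithmetic (ranks doubled to integers), so
  the result equals brute-force enumeration bit for bit; restricted to
  n ≤ 25. Only the exact distribution reproduces published small-sample
  values like 2/1024 ≈ 0.0020 at n = 10 — a normal approximation does not.
* **Paired t** and **two-condition repeated-measures ANOVA**: the latter
  is computed through F = t² and the F(1, n − 1) survival function; the
  identity with the paired t probability is asserted in tests (with
  statsmodels' AnovaRM as an independent oracle).
* **Bonferroni**: min(1, m·p) with m = 3 — the full family of paradigm
  pairs (arrow/picture, arrow/video, picture/video) even though only the
  two arrow-vs-proposed pairs are tabulated, which is the convention the
  published corrected columns follow (each is 3 × the ANOVA column). The
  correction is applied to the ANOVA probability.
* All tests are two-sided; α = 0.05.

Degenerate comparisons (all differences zero, zero variance) raise by
default; the batch pipeline records NaN probabilities instead so that a
ceiling-accuracy synthetic condition cannot abort a whole run.

## Pipeline and reproducibility

`run_experiment` treats the acquisition paradigm as a data attribute: one
identical processing chain for all paradigms, with per-paradigm ERD-depth
overrides as the mechanism for synthesizing "paradigm improves
separability" scenarios. Every random stage traces to the config seed;
rerunning a config reproduces all CSV outputs byte for byte, and the
manifest records the config hash and library versions.

## Problem sizes

The shipped benchmarks run at the study's session scale (40 trials/class,
16 channels, 250 Hz, T = 2 s, 10-fold CV). The permutation null uses 100
permutations; the depth sweep averages 10 seeds per depth at three depths;
the paired-t calibration uses 10⁴ replicates. The full test suite and the
acceptance script each complete in a few minutes on one CPU.

## Known limitations

* Whether the original analysis filtered causally or zero-phase, refit CSP
  per window or once per trial segment, and repeated its cross-validation
  is not established; this package's contracts (zero-phase; per-window
  refit inside folds; a single 10-fold pass) are documented choices, and
  the session-accuracy statistic could shift slightly under the
  alternatives.
* EDF export quantizes to 16 bits with per-channel scaling recorded in the
  header (reconstruction error ≤ half a quantization step); events travel
  in a CSV sidecar because plain EDF has no annotation stream. The native
  plain-text format is lossless.
* ERD/ERS maps inherit epoch-edge filter transients (first/last ~1 s);
  maps are descriptive, with no significance masking.
* The exact Wilcoxon implementation conditions on the observed (possibly
  tied) ranks; its null is the sign-assignment distribution, the standard
  convention for small paired samples.
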