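# Methods

This note documents the models and numerical choices behind rutvox, what
the synthetic generators do and do not emulate, and the known limits of
what the test suite demonstrates.

## Grunt and soundscape synthesis

A grunt series is rendered as a harmonic stack at the fundamental
f₀ ∈ (0, 100) Hz with a glottal-like 1/k² rolloff, shaped by Lorentzian
resonance bumps at 2–3 formant frequencies (all ≤ 2.5 kHz, bandwidth
~90 Hz). The fundamental is forced to stay the single dominant spectral
peak, and ≥90 % of energy lies below 1 kHz — the two spectral facts the
detector relies on. An amplitude envelope repeats individual grunt pulses
at `pulse_rate_hz` (duty cycle 0.75 with a voiced floor of 0.15 between
pulses) under 50-ms attack/decay edges. Rendering is a pure function of
the spec; scenes add seeded backgrounds:

* **wind** — pink noise low-passed at 400 Hz with slow (0.05–0.45 Hz)
  gust modulation; the dominant real-world confounder, since both wind
  and grunts concentrate energy at low frequency;
* **biophony** — sparse 1.5–6 kHz chirps over faint band-passed noise
  (mostly removed by the 1 kHz low-pass, as in the field pipeline);
* **distractor calls** — tonal sweeps confined to a band inside the
  grunt range but lacking the low-frequency harmonic stack; they fall
  inside absence boxes.

One presence box covers each grunt series over `[onset, onset+duration)`;
absence boxes tile the gaps. Overlapping presence events are rejected so
frame-level ground truth is unambiguous.

**Benchmark tiers.** The recorders' SNR is not well characterized, so
tier defaults are chosen for a well-posed desk-scale study: the `default`
tier uses grunt amplitudes 6–17× the background RMS, test scenes of 240 s
with 1–3 grunt series of 18–35 s separated by ≥20 s, and training scenes
of 120 s with 3–5 series of 6–20 s. The long-series/sparse-scene design
is deliberate: scoring is frame-based while detection windows are 4 s, so
every event boundary can contribute up to ~3 s of false-positive "halo"
from partially overlapping windows; the halo is O(1) per event while true
positives grow with series length, which keeps frame metrics reflective
of detection quality rather than boundary discretization. The `hard`
tier lowers SNR and adds distractors; `dense` packs ≥50 short series
into a scene and is intentionally hostile to frame-based precision
(halos bridge short gaps).

## Preprocessing

Zero-phase 8th-order Butterworth low-pass at 1 kHz (applied
forward-backward; the documented response is the squared Butterworth
magnitude), then polyphase downsampling to 8 kHz (Nyquist 4 kHz).
Training windows of exactly 4 s start at each annotation box's start
time and advance by 1 s while they still fit inside the box; boxes
shorter than a window contribute the single window at their start, and
windows overrunning end-of-file are zero-padded so the CNN input shape
is fixed. Mel spectrograms use centered framing (⌊N/hop⌋+1 = 126 frames
at N = 32 000, hop 256), a Hann window of 1024 samples, and 128
triangular mel filters from 0 to 4000 Hz. Power is converted to dB and
min–max normalized to [0, 1] per segment (a constant segment maps to
zeros); exponent channels S¹, S³, S⁵ then give three contrast views of
the same image. Normalization is per-segment by design: the exponent
trick is only meaningful on a bounded, contrast-normalized scale.
Augmentation re-slices the source audio at a uniform shift of magnitude
< 2 s rather than rolling the tensor, and class balancing subsamples the
majority class without replacement.

## Detector

The classifier is a compact CNN written on numpy: an input 2×2 average
pool (mel spectrograms are oversampled relative to grunt texture),
three 3×3 conv + ReLU + 2×2 max-pool blocks (8/16/32 channels), global
average pooling and a 32-unit hidden layer with two softmax outputs
(~7 k parameters). Convolutions are im2col matrix products; training is
Adam (lr 10⁻³, batch 32) on softmax cross-entropy, deterministic for a
fixed seed on a single thread, with backpropagation verified against
finite differences in the test suite. A pretrained image backbone is not
provided — transfer learning would require a deep-learning framework —
and the config rejects that option explicitly; at the synthetic
benchmark's scale the compact network saturates the task within 10
epochs.

Whole-file inference slides a 4-s window 1 s at a time until the entire
recording is processed (a trailing partial window is zero-padded). A
frame of 1 s is positive when **any** covering window exceeds the 0.5
threshold — the recall-maximizing semantic appropriate when detections
are manually verified downstream; a majority rule is available. Maximal
positive runs become detection events scored by the mean presence
probability of their windows.

## Evaluation

Frame-based confusion counts on 1-s frames (the inference hop): a frame
is truth-positive if it overlaps any presence box and
predicted-positive if it overlaps any event. Recall = TP/(TP+FN),
precision = TP/(TP+FP), accuracy = (TP+TN)/total, F1 = 2PR/(P+R).
Ratios with zero denominators are reported as NaN with an explicit flag,
never silently zero. Files are pooled by micro-average (metrics of the
summed counts), with a macro row alongside.

## Hourly aggregation and peak-rut backdating

Detection events are split at clock-hour boundaries and their durations
summed per hour; the proportion is grunt seconds / 3600. Hours touched
by the recording appear (with zeros when silent); unrecorded hours are
omitted rather than zero-filled. Edge hours only partially covered by a
recording still use the 3600-s denominator, which undercounts activity
in those hours — callers with many short files should trim to whole
hours. The peak rut date is the mean calving date (mean day offset,
half rounded up) minus the 221-day gestation length.

## Hierarchical beta GAM

The response g ∈ [0, 1] is modelled as Beta(μθ, (1−μ)θ) with
logit(μ) = β₀ + Status + f_i(Day) + g_i(Hour) + b_i. Exact zeros are
moved to 2.2 × 10⁻¹⁴ (ones symmetrically to 1 − 2.2 × 10⁻¹⁴) before
fitting. Status is a two-level factor that may vary record by record
(males gain and lose harems within a rut); records with unknown status
are excluded.

* **Hour smooth**: cyclic cubic regression spline, k = 10 knots over
  [0, 24] with the value/second-derivative parameterization, so the
  curve and its first two derivatives match at midnight exactly.
  Constants span the penalty null space.
* **Day smooth**: cubic B-spline basis of size k = 22 with the exact
  integrated-squared-second-derivative Gram penalty (2-point
  Gauss–Legendre per knot span, exact for the piecewise-quadratic
  integrand); linear trends are unpenalized. Prediction outside the
  observed day span is clamped and flagged as extrapolation.
* **Hierarchy**: each individual gets its own hour smooth and day smooth,
  each carrying its own smoothing parameter ("varying wiggliness"),
  plus ridge-penalized individual intercepts sharing one variance
  component. Smooths are centered (sum-to-zero over the data) for
  identifiability against the global intercept.

**Fitting.** For fixed smoothing parameters, coefficients maximize the
penalized beta log-likelihood by Fisher-scoring Newton steps with step
halving; θ is profiled by bounded 1-D likelihood optimization, and the
two alternate to convergence. Smoothing parameters follow the
generalized Fellner–Schall update
λ_j ← λ_j · [rank(S_j)/λ_j − tr(V S_j)] / (β̂ᵀS_jβ̂) with
V = (XᵀWX + S_λ)⁻¹, a fixed-point ascent of the Laplace-approximate
(REML-type) marginal likelihood, iterated until log-λ changes fall below
0.02 (λ clamped to [10⁻⁶, 10⁸]; a λ marching to the ceiling means
"smooth to the null space" and does not block convergence).
Non-convergence raises with the iteration trace rather than returning a
partial fit. On a shared-structure test problem the fit agrees with
mgcv's `betar` REML GAM to ~0.01 on the status coefficient and ~0.01 on
deviance explained (asserted at 0.2/0.1 in the suite).

**Summaries.** The posterior covariance V yields pointwise 95% bands for
the smooths and the status contrast's SE; effective degrees of freedom
are tr(V XᵀWX) per block. Deviance is 2(ℓ_sat − ℓ̂) where the saturated
ℓ maximizes each observation's likelihood over μ at the fitted θ — for
the beta family this is the digamma-score inversion
ψ(μθ) − ψ((1−μ)θ) = logit(y), not μ = y; with offset-adjusted boundary
observations the naive choice is not an upper bound and deviance
explained could leave [0, 1]. The null deviance uses the common-mean MLE
at the same θ, so a null model fitted to its own data explains zero
deviance. The adjusted r² is 1 − (1 − r²)(n − 1)/(n − 1 − edf) with
r² the squared correlation of response and fitted mean; beta-GAM r²
definitions are package-specific and this one is not claimed identical
to any other. Diagnostics are quantile residuals Φ⁻¹(F_Beta(y; μ̂θ)),
a residual-vs-fitted table, and per-individual residual ACFs.

**Wilcoxon rank-sum.** The statistic is the Mann–Whitney U of the first
group reported as W (R's convention). The two-sided p is exact by full
enumeration of group assignments for n₁ + n₂ ≤ 20 and otherwise uses
the normal approximation with tie correction and continuity correction.

## Behavioural generator

`synth_behaviour_series` draws hourly records from the same model the
fit assumes: a periodic-cubic default diel curve with its trough just
before dawn (~06:00) and elevated grunting ~09:00–21:00, a Gaussian
seasonal bump peaking at day 0 with ~6-day scale, a dominance contrast
(default +1.5 logit), N(0, 0.4²) individual intercepts, θ = 8 and a
baseline logit of −2.2 (≈10 % baseline grunting). Status trajectories
switch between dominant and subdominant at random days (default one
switch per individual), which identifies the status effect
within-individual. `zero_inflation` mixes in exact zeros; its default is
0 because uniform zero inflation is deliberate misspecification of the
beta model — at 5 % inflation the recovered status contrast attenuates
by ≈0.4–0.5 logit with the 2.2 × 10⁻¹⁴ offset, a limitation users
should expect on zero-heavy real data too.

## Problem sizes and determinism

Desk-scale defaults throughout: the detection benchmark is 10 training +
4 test scenes (~36 minutes of audio, ~700 balanced training windows,
10 epochs, a few minutes on one CPU core); the recovery study is 10
seeds × 2,000 records (seconds per fit). Every random choice flows from
an explicit integer seed through `numpy.random.default_rng`; audio
rendering, training and inference are bit-reproducible on a fixed
single-threaded BLAS configuration, and the pipeline manifest records
SHA-256 hashes of every artifact.

## What passing tests do and do not show

The synthetic soundscapes share the real problem's geometry (spectral
overlap of wind and grunts, long and short series, annotation-box
training) but not its messiness: no recorder damage, no collar rubbing,
no conspecific calls at close range, no amplitude drift as animals move.
Detection scores on the benchmark therefore bound what the architecture
can do under clean conditions rather than predict field performance.
Likewise the behavioural generator matches the fitted model's form
(except for optional zero inflation), so parameter recovery demonstrates
the estimator's correctness, not robustness to real-world
misspecification such as autocorrelated residuals within hours or
status-dependent recording gaps.
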