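# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Task geometry and the synthetic generator

The simulated task is a two-location interception paradigm: an observer
stands on a line 4 m from a front wall; balls launch from one of two wall
holes separated by 21.5° of visual angle as seen from the line (lateral
offset ±4·tan(10.75°) ≈ ±0.76 m), travel a straight line at an average
10 m/s, and arrive at chest height (1.36 m) with a small lateral offset
(0.30 m, same side as the release) so they are reachable with a racquet.
Each participant completes 6 blocks of 20 trials with left/right mixes
50/50, 50/50, 90/10, 70/30, 30/70, 10/90 — block composition is exact
(round-half-up counts, shuffled order), not sampled.  A uniform 0–5 s
delay separates the end of the warning tones from ball release.  The eye
origin is fixed at (0, 1.6, 0) m, a standing eye height; recordings are
sampled at 120 Hz.

**Trial end.**  A recording ends at the *interception event*: the crossing
of a racquet plane 0.5 m in front of the standing line (0.35 s after
release for the default geometry).  On hit trials the virtual ball
disappears there; beyond it the ball's angular velocity relative to the
head grows without bound (≈1,900°/s at a 0.3 m pass distance), which
neither human pursuit nor any velocity-based event detector can follow.
The full wall-to-line flight still takes `release_distance / ball_speed`
= 0.4 s — the observer's reaction window.

**Gaze model.**  Gaze is generated in two phases with known ground truth:

* *Pre-onset*: with a per-participant commitment probability, gaze sits on
  a predicted release location (sampled from the block's left/right
  probability), otherwise at the central pivot position with Gaussian
  per-trial drift (SD 2° by default).
* *In flight*: eye yaw/pitch follow the ball's angles delayed by `lag` and
  scaled by `pursuit_gain` about the pre-onset position.  When the
  gaze–ball error exceeds `catchup_threshold` (6°), a minimum-jerk saccade
  is injected that lands on the ball's position extrapolated 150 ms ahead
  — the predictive targeting typical of interceptive gaze.  Saccades
  launch only while the ball's angular speed is below ≈28°/s (early
  flight) and not in the final 100 ms: later in flight the ball itself
  sweeps faster than any plausible catch-up saccade's sustained velocity,
  so such jumps are both behaviorally implausible and mathematically
  invisible to a velocity-ratio detector.  Pivot-strategy trials inject no
  saccades; their pursuit gain is low (0.15) rather than zero, standing in
  for residual gaze drift toward the ball.

  Injected saccade durations are drawn from 55–60 ms.  Human catch-up
  saccades of 6–10° can be faster (≈35–45 ms), but the standard detection
  rule (speed > 40°/s on ≥5 consecutive frames at 120 Hz) can only ever
  certify events that stay above threshold for ≥42 ms; the generator uses
  the upper end of the physiological range so that every injected event is
  in principle detectable, which is what makes exact count-recovery tests
  meaningful.

* *Measurement noise*: additive Gaussian angular noise, band-limited at
  10 Hz and rescaled to `gaze_noise_sd` (0.5° default, matching
  consumer-VR tracker accuracy).  Sample-wise white noise is *not* used:
  at 120 Hz a 1° white process has a second-difference SD near
  35,000°/s², an acceleration spectrum no physical tracker produces, and
  it would saturate the median-absolute-acceleration threshold.  Dropouts
  (1% of samples in runs of 1–3 frames, values frozen at the last valid
  sample) exercise the detector's missing-data rule.

**Outcome model.**  Interception success is Bernoulli with logit
`b0 + skill_i + b_err·(mean angular error) + b_exp·expectedness`, where
`skill_i ~ N(0, 1.1)` is a per-participant motor-skill intercept,
the angular error is the mean great-circle gaze–ball angle over the
flight, and expectedness is the block probability of the realized side.
Defaults (`b0 = 0.9`, `b_err = −0.01`/deg, `b_exp = 0.5`) give an overall
hit rate near 0.75 with deliberately *weak* tracking effects and strong
participant-level variance — the regime the analysis stage is designed to
resolve (conditional R² ≈ 0.30, marginal R² < 0.01 on simulated data).

**Randomness.**  All draws flow from one seed through fixed
`SeedSequence` substreams per participant, so datasets are bit-identical
across runs and machine-independent.

## Preprocessing

Angles use the convention: yaw = atan2(x, z) about the gravity-aligned
vertical axis (0° straight ahead, positive rightward), pitch = elevation
from the horizontal eye-height plane (+90° up).  Denoising is a 3-sample
moving median (shrinking to a 2-sample mean at the edges) followed by a
zero-phase second-order Butterworth low-pass — 50 Hz for the saccade
channel, 15 Hz for positional metrics.  Zero-phase (forward–backward)
filtering is used so the filter itself adds no tracking lag.  Invalid
samples are linearly interpolated before filtering for stable filter
state, and stay flagged invalid downstream.

Differentiation is central-difference (one-sided at the ends); invalidity
spreads one frame each side.  The combined-plane angular speed is
`sqrt((yaw_rate·cos(pitch))² + pitch_rate²)`: yaw circles shrink by
cos(pitch) away from the horizon while meridians are great circles, so the
convergence correction belongs on the yaw term (verified against
brute-force great-circle rates on the unit sphere).  At this task's small
pitch range the correction is near-identity.

**Filter-edge exclusion.**  Because recordings end at the interception
event, the Butterworth boundary transient overlaps the last frames of the
flight — exactly where ball angular velocity is largest.  The final 6
frames (50 ms) are therefore excluded from velocity-based metrics; without
this, those few contaminated samples dominate the lag cross-correlation
(errors up to hundreds of ms on otherwise perfect data).

## Oculometrics

* **Saccade detection** (50 Hz channel, combined-plane speed): candidates
  are runs with |acceleration| > 5× the median absolute acceleration over
  the flight window (computed per trial, robust to between-trial amplitude
  differences).  Runs closer than 20 ms merge — a single minimum-jerk
  saccade produces two acceleration lobes around a quiet middle.  A
  candidate is kept only if gaze speed exceeds 40°/s on ≥5 consecutive
  frames while also exceeding 1.2× the ball's speed (rejecting pursuit of
  the ball's own fast final sweep), and only if the 3 preceding frames are
  valid (interpolation across a gap can fake a burst).  Event bounds
  extend to the nearest local minima of |acceleration| on each side; a
  `boundary_mode="signed"` flag switches to the preceding maximum /
  following minimum of the signed profile, which excises only the middle
  of the saccade and is kept for comparison.

* **Coherence and lag** (15 Hz channel): Pearson correlation of eye and
  ball yaw velocities at every integer-frame lag within ±250 ms
  (overlapping segments only, ≥10 valid pairs), reporting the maximum and
  its lag; ties break toward zero lag; zero-variance windows return NaN.
  Velocities rather than positions are correlated — position series in
  this task are near-monotone ramps whose correlation is high at every
  lag; a `xcorr_signal="position"` flag provides the position variant.
  Single-trial lag estimates under noise remain jittery for the same
  reason (broad velocity autocorrelation over a 0.35 s window); the
  pipeline's unit of inference is the per-participant mean over ~120
  trials.

* **Pursuit gain** (15 Hz channel): saccade intervals are removed, then
  gain = mean(eye velocity projected on the ball's motion direction) /
  mean |ball velocity| over the closed-loop window, 140 ms after release
  to the interception event.  Ratio of means avoids instability at ball
  velocity zero crossings; the signed projection equals the rectified
  ratio on clean traces but stays unbiased under zero-mean tracker noise,
  where rectified speeds inflate low gains (+0.21 at gain 0.25 with 1°
  noise, versus +0.016 for the projection).  Known property: for strongly
  lagging observers the metric reads low by construction, because the
  delayed eye never reaches the ball's late-flight velocities inside the
  window; gain-recovery experiments therefore impose lag 0, and at fixed
  lag the metric is monotone in true gain.

* **Pre-onset prediction**: gaze yaw averaged over the 50 ms ending at
  tone termination (the last moment before the ball can appear), mapped to
  a normalized coordinate linear in wall position with the release
  locations at ±0.8 (u = 0.8·tan(yaw)/tan(10.75°)).  |u| ≤ 0.4 —
  the central half of the inter-location space, 10.85° of visual angle by
  exact trigonometry (≈10.9°) — is nonpredictive; otherwise the side of
  sign(u) is the prediction, scored against the realized release side.
  The partition of the real line is exhaustive and exclusive.

## Inference

Variables are screened by Winsorizing: values beyond mean ± 3 SD (both
computed on the original sample, making the operation idempotent) move to
the nearer boundary.  Note a lone outlier among n values can sit at most
(n−1)/√n SDs from the mean, so tiny samples are never clipped.

Success models are binomial mixed GLMMs fit with statsmodels'
`BinomialBayesMixedGLM` (variational Bayes; weak N(0, 2²) priors), with a
participant random intercept or intercept + slope.  Wald-style p-values
and 95% CIs use the posterior mean and SD of each fixed effect; under null
simulations the resulting test is near-nominal (type-I ≈ 0.03–0.065 at
α = 0.05 over 200 replicates) and a true standardized slope of 0.5 is
recovered to ±0.01 on average over 50 replicates.  Standardized betas
multiply each coefficient by its predictor's SD (binary predictors and the
binary outcome stay unscaled).  Marginal and conditional R² use the
variance decomposition var(Xβ) / (var(Xβ) + var(random) + π²/3) with the
logit residual variance fixed at π²/3.  No multiple-testing correction is
applied; the analyses are exploratory and the docs say so.

Group contrasts use an independent-samples t test, switching to Welch's
form when a two-sided F-ratio test rejects equal variances at 0.05;
Cohen's d uses the pooled SD in either case.

## Strategy analysis

Participant profiles are per-participant means over non-missing trials of
the four tracking metrics, the interception rate, and the prediction
proportion (committed predictions over classified trials).  The mean split
labels participants *predictive* when strictly above the grand-mean
prediction proportion, else *pivot* (ties to pivot); labels are invariant
to affine rescaling of the proportion.

Classical (Torgerson) MDS embeds the z-scored 4-metric profiles:
double-center the squared Euclidean distance matrix, eigendecompose
B = −½·J·D²·J, scale eigenvectors by √eigenvalue, report variance
proportions over the positive spectrum.  Z-scoring is the default so no
metric dominates through its units (a raw mode exists).  Signs are fixed
(largest-|loading| positive, then oriented so the predictive-group mean is
positive on each axis) for reproducible plots.  Group separation along
dimension 1 is quantified by the best single-threshold classification
accuracy.

## Validation battery and problem sizes

`gazeflight.validation` defines the standard experiments, run both by the
test suite and by `scripts/acceptance.py`:

* gain recovery at true gains 0.25/0.5/0.8/1.0 — noise-free single trials
  and 100-trial means at 1° noise;
* lag recovery at 25/50/100 ms imposed delays (noise-free, gain 1);
* saccade count recovery over 24 noise-free and 40 noisy trials with the
  full injector active;
* brute-force oracle agreement for the lagged-correlation search and MDS
  distance reproduction;
* mixed-model calibration from a known random-intercept logistic model at
  20 participants × 60 trials (200 null replicates for type-I error, 50
  replicates for slope recovery) — a deliberately reduced design that
  keeps the calibration experiment quick while leaving ~1,200
  observations per fit;
* a full-scale study replication at 41 participants × 120 trials with a
  22/19 strategy mix, checking exact mean-split recovery, ≥90% MDS
  dimension-1 separability of strategies, and the *absence* of comparable
  separability for a high/low-performance split.

## What the synthetic data does and does not show

The generator reproduces the study design's geometry, schedule,
two-strategy structure, weak tracking–success coupling and strong
participant-level success variance, and it gives every estimator an exact
ground truth.  It does not emulate: head movement (the eye origin is
fixed), vergence or depth-dependent gaze errors, blink dynamics,
main-sequence variability of saccades, pursuit onset latency or
open-loop pursuit, learning across blocks, or hand/racquet kinematics.
Strategy clusters are cleaner than human data (synthetic group effect
sizes |d| ≈ 3–10 versus ≈1–1.5 in comparable human samples), so passing
the clustering tests demonstrates correctness of the estimators and the
analysis chain, not that real populations separate this sharply.
Velocity-rule saccade detection at 120 Hz is inherently blind to small or
late-flight saccades; detected counts should be read as "large, early,
detectable saccades".
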