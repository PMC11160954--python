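# gazeflight

Analysis pipeline for eye-tracking studies of **manual interception in
virtual reality**, where a ball launches from one of two wall locations and
the observer must strike it within a few hundred milliseconds.  The package
takes raw per-trial time series — a cyclopean gaze direction (unit vector),
ball position, and validity flags sampled at 120 Hz — and produces:

* **per-trial oculometrics**: saccade events, tracking coherence and lag,
  closed-loop smooth-pursuit gain, and a pre-onset prediction class
  (did gaze sit on a release location before the ball appeared, or at a
  central "visual pivot"?);
* **trial-level inference**: mixed-effects logistic regressions of
  interception success on the tracking metrics, with marginal/conditional
  R² and standardized betas;
* **participant-level strategy analysis**: profile aggregation, a mean
  split into *predictive* vs *visual pivot* strategies, classical MDS of
  tracking profiles, and strategy-group comparisons;
* a **synthetic-task generator** that emulates the full study design
  (two release locations 21.5° of visual angle apart viewed from 4 m,
  10 m/s balls, 6 blocks × 20 trials with skewed left/right mixes, 0–5 s
  onset delays) with controllable pursuit gain, lag, saccade rate and
  tracker noise — so every estimator is validated by parameter recovery
  against known ground truth.

## The measurements

With yaw/pitch the head-centric angles of gaze and ball (yaw 0° = straight
ahead, positive rightward; series median-filtered then zero-phase
Butterworth low-passed at 50 Hz for saccade detection and 15 Hz for
positional metrics):

* **Tracking coherence and lag** — the peak of the lagged Pearson
  correlation between eye and ball yaw velocities over the flight window,
  and the delay (s) at which it occurs (positive = eye trails ball).
* **Saccades** — intervals where |gaze acceleration| exceeds 5× its median
  absolute value, gaze speed exceeds 40°/s on ≥5 consecutive frames and is
  ≥20% faster than the ball, not preceded by missing data; bounds at the
  quiet points of the acceleration profile.
* **Pursuit gain** — saccade-free eye velocity over ball velocity
  (ratio of means, eye velocity projected on the ball's motion direction)
  during closed-loop tracking, from 140 ms after release to interception.
* **Pre-onset prediction** — mean gaze yaw over the 50 ms before the
  warning tones end, mapped to a normalized wall coordinate with the
  release locations at ±0.8; |u| ≤ 0.4 (the central half of the
  inter-location space, ≈10.9° of visual angle) is nonpredictive.

Success models are binomial GLMMs with a participant random intercept
(optionally random slopes), fit by variational Bayes (statsmodels);
variance explained uses the marginal/conditional R² decomposition for
logit models with residual variance π²/3.

## Worked example

```python
import gazeflight as gf

cfg = gf.SimConfig(n_participants=20, rng_seed=3)   # study-like task
recordings = gf.simulate_dataset(cfg)
metrics = gf.metrics_table(recordings, gf.default_geometry(cfg))
for p in ["coherence", "lag", "gain", "n_saccades"]:
    metrics[p] = gf.winsorize(metrics[p].to_numpy())
res = gf.fit_success_model(metrics, ["coherence", "lag", "gain", "n_saccades"])
print(res.summary_frame().round(3))
print(f"marginal R2 {res.marginal_r2:.3f}, conditional R2 {res.conditional_r2:.3f}")
```

prints

```
             coef  ci_lower  ci_upper      p  std_beta
intercept   1.347     1.250     1.444  0.000       NaN
coherence  -0.133    -0.253    -0.013  0.030    -0.026
lag         0.225    -0.366     0.815  0.456     0.036
gain       -0.423    -0.791    -0.054  0.024    -0.076
n_saccades -0.187    -0.396     0.021  0.079    -0.187
marginal R2 0.003, conditional R2 0.302
```

— tracking metrics carry statistically detectable but *weak* information
about interception success (tiny standardized betas, marginal R² below
0.01), while most explainable success variance is between participants
(conditional R² ≈ 0.30).  Running the strategy stage on the full 41-
participant design (`python examples/04_strategy_clustering.py`) splits
participants 22 predictive / 19 pivot, recovers the generator's strategy
assignment exactly, and embeds the tracking profiles so that MDS dimension
1 (≈90% of variance) separates the strategy groups completely while a
high/low-performance split does not separate at all.

The `examples/` directory has one short script per capability:
simulation and I/O, per-trial metrics, success models, strategy clustering.

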