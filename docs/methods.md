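# Methods

## Measurement model

The device applies a known, mechanically determined pressure to the digital
artery and reads the resulting pulse amplitude optically. Three chained
models describe it:

**Mechanics.** A linear spring with stiffness k = 0.49 N/mm, preload 0.1 N
and 6.7 mm of travel gives force F(x) = 0.1 + 0.49·x N at compression x mm.
Spread over the 10-mm circular contact (area 78.54 mm²), and with
1 mmHg = 133.322 Pa, the contact pressure spans 9.55 mmHg at rest to
315 mmHg at 3.3 N — below any diastolic and above any plausible systolic
pressure, which is what makes the staircase sweep informative. The model
keeps full precision internally (full-travel force 3.383 N); the commonly
quoted 3.3 N endpoint is treated as a rounded display value, and the 315
mmHg figure corresponds to that rounded input. Forces and pressures are
strictly increasing in compression, and `compression_from_force` inverts the
chain to machine precision.

**Optics (synthetic).** The pinhole projection is modelled as a filled disc
whose diameter grows linearly with spring compression from `d_min` to
`d_max` pixels, the simplest mapping consistent with the projection growing
as the pinhole nears the camera. In-disc brightness is
`skin_baseline − A(p)·w(φ)`: more blood absorbs more light. The surround is
a flat dark level (default 2) — the clip is a sealed enclosure, so outside
the projection the sensor sees an essentially constant black level — while
i.i.d. Gaussian sensor noise (default sd 2 grey levels) is applied within
the disc, where there is signal. Keeping the background single-valued
matters: the app's area measure thresholds the *histogram-equalized* frame
at 20, and equalization maps the (majority) background bin to 0 only when it
is concentrated; a background with multi-bin noise would smear upward
through the CDF and the fixed threshold would count it as disc. The flat
background reproduces the regime in which the deployed algorithm operates.

**Physiology (synthetic).** The pulse amplitude envelope is
`A(p) = g · exp(−(p − MBP)² / 2σ²) · s(p)` with per-subject gain g (grey
levels) and width σ (mmHg), where `s(p)` is a smoothstep falling from 1 to 0
over the 5 mmHg below SBP and exactly 0 at and above it — arterial
occlusion stops the pulse. The Gaussian-envelope form is the standard
oscillometry idealization; the hard collapse above SBP is the qualitative
feature the estimator exploits. The waveform w(φ) is a raised cosine with
period 60/HR s, normalized to unit peak-to-trough (an optional
second-harmonic dicrotic notch is off by default). Ground truth always
satisfies MBP = SBP/3 + 2·DBP/3.

## Guided protocol

Twenty force targets are spaced endpoint-inclusively over 5–95 % of the
force scale (the scale itself is calibrated per session from the disc
diameter at rest and at full compression, and is linear in diameter). The
state machine is RED out of band, YELLOW within ±2 percentage points of the
target, GREEN after 2 s of continuous hold, and records for 5 s; any
violation while YELLOW/GREEN discards the partial level. Violations are the
movement signal — no separate accelerometer model exists. Completion times
are computed at exact window boundaries (enter + hold + record), so an ideal
user takes exactly 140 s and a violation t seconds into GREEN costs exactly
hold + t extra. The user model has three dials: acquisition delay per level,
within-band tremor (truncated so it cannot cause accidental violations on
its own), and a per-attempt violation probability; a configurable attempt
cap marks sessions incomplete.

## Signal processing choices

- **Area**: count of pixels strictly above 20 after global integer
  histogram equalization (CDF lookup table with cdf-min normalization; a
  single-valued frame passes through unchanged). The equalization LUT is
  implemented here because the integer 8-bit variant with cdf-min
  normalization is the behaviour specified, and float-based library
  equalizers do not reproduce it.
- **PPG**: mean of raw pixel values in the closed band [20, 254] — computed
  on the un-equalized frame; saturated pixels are excluded; an empty
  selection yields NaN and a logged warning.
- **Force display smoothing**: 4th-order zero-phase Butterworth low-pass at
  0.4 Hz, below the slowest plausible heart rate (36 bpm = 0.6 Hz).
- **Cardiac band-pass**: 4th-order zero-phase Butterworth, 0.5–10 Hz;
  requires ≥ 20 Hz sampling, with the upper edge capped at 0.95·Nyquist when
  it would touch it.
- **Pulse averaging**: peaks via prominence ≥ 0.5 grey levels with minimum
  spacing of one beat at 180 bpm; a pulse is complete when troughs flank its
  peak inside the 5-s window; amplitude = peak − mean(flanking troughs).
  Windows with no complete pulse contribute a flagged zero.
- **Oscillogram**: one point per level at the median recorded force scale;
  pressure from the mechanics chain; endpoints dropped (finger lift-off at
  the bottom, spring bottoming-out at the top), remaining 18 amplitudes
  min–max normalized to [0, 1] (a divide-by-max variant is available).
- **Screening**: excluded if the raw oscillogram maximum is below 1 grey
  level (no usable pulse; precedence over other rules) or the reference
  pulse pressure exceeds 80 mmHg (strictly greater).

## Estimator

Stage 1 fits two independent single-target LASSO models (SBP, MBP) on the 18
normalized amplitudes; features are already on [0, 1] so no further
standardization is applied. The penalty is selected per training fold by
5-fold inner cross-validation over a 30-point logarithmic grid (1e−4 to 10);
a shared-penalty multi-target variant sits behind `multi_target=True`.
Stage 2 is OLS of DBP on the stage-1 predictions *for the same training
subjects* (no nested holdout — documented choice). Under perfect stage-1
predictions the reference identity forces coefficients (−0.5, +1.5) and zero
intercept, which the tests verify. If stage-1 predictions are constant
(penalty → ∞) stage 2 degenerates gracefully to an intercept-only model;
non-constant exact collinearity raises an error rather than silently picking
one of infinitely many solutions.

Validation is leave-two-subjects-out: the sorted roster is randomly paired
with a recorded seed (pairing therefore depends only on the roster and the
seed, not input order), both stages are refitted from scratch per fold, and
MAE ± sd of absolute error, bias, 95 % limits of agreement
(bias ± 1.96·sd of error) and Pearson r are computed over held-out
predictions only.

## What the synthetic cohorts do and do not show

The population model draws SBP ~ N(116.8, 20.3) and DBP ~ N(73.5, 12.3)
mmHg independently with rejection to a pulse pressure in [15, 80] (forced
out-of-range subjects excepted), heart rate ~ N(72, 10) truncated to
[36, 180] bpm, perfusion gain uniform on [15, 45] grey levels, envelope
width ~ N(22, 3) mmHg and skin baseline uniform on [150, 210]. Pulseless
subjects get gain 0.05, below the 1-grey-level screening floor even after
the in-disc averaging leaves residual noise of order noise_sd/√(disc
pixels).

Passing the recovery tests (cross-validated SBP MAE < 8 and DBP MAE < 6 mmHg
on the default 60-subject cohort) shows the pipeline is internally
consistent — the estimator can read back the pressures the generator
encoded through the full frame → feature → oscillogram chain. It does not
certify clinical accuracy: the generator omits motion artifacts beyond
force-band violations, skin-tone and illumination spectra, envelope-shape
diversity beyond the Gaussian family, sensor rolling shutter, and every
physiological confounder that makes real fingertip oscillometry hard.
Accuracy numbers on synthetic cohorts are parameter-recovery statements
only.

## Problem sizes and determinism

Default frames are 128×128 px at 30 fps; cohort-scale work uses the
64×64-px reduced optics at 20 fps and the signal-level fidelity (identical
physics, rasterisation skipped), which keeps full-cohort simulations in the
tens of seconds. All randomness flows through `numpy.random.default_rng`
seeds threaded from a single master seed per run; sessions are bit-identical
for a fixed seed, and every CSV output records version, seed and config
hash.
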