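# Methods

This note documents the models, parameter choices and numerical details
behind `prefall`, and what the synthetic experiments do and do not show.

## Signal model and preprocessing

Input is a 6-axis waist IMU stream: acceleration in g, angular velocity
in deg/s, nominally 100 Hz (SisFall recordings are processed at their
native 200 Hz rather than resampled; the filter and the coincidence
window are specified in physical units and are therefore rate-aware).
Units are converted at the I/O boundary; the internal maths never mixes
m/s² or rad/s.

All detector features are computed on a low-pass-filtered copy of the
stream. The filter is a 2nd-order Butterworth with a 5 Hz cutoff.
Because a pre-impact trigger cannot use future samples, the default
realisation is **causal** (single pass, initialised at the steady-state
response to the first sample so constants pass through unchanged); a
zero-phase forward-backward variant is selectable for offline analysis.
The causal filter's ~40–50 ms group delay at low frequency is part of
the detector's latency budget. The first 0.5 s of every trial is
excluded from detection to cover filter and estimator transients
(configurable `warmup_s`).

## Orientation estimation

Roll φ (frontal plane) and pitch θ (sagittal plane, backward positive)
are estimated by a complementary filter with PI feedback:

* body rates → Euler-angle rates through the kinematic map
  (φ̇ = ωx + sinφ tanθ ωy + cosφ tanθ ωz; θ̇ = cosφ ωy − sinφ ωz);
* per axis, error e = accelerometer inclination − current estimate;
  integral accumulator += ki·e·dt (clamped to ±20°); corrected rate =
  Euler rate + kp·e + accumulator; explicit Euler step at dt = 1/rate.

Parameter choices (all config-exposed):

* **kp = 1.0 (1/s), ki = 0.1 (1/s²).** No gain values are published for
  this class of filter at this placement, so the defaults were chosen to
  satisfy two closed-form requirements: a static angle offset decays
  with time constant 1/kp ≈ 1 s (fast enough to matter within a trial,
  slow enough that impact transients average out), and the closed loop
  (s² + kp·s + ki) is overdamped with the slow mode at ≈ 0.11/s, giving
  full cancellation of constant gyro bias within ~30 s. Both properties
  are asserted in the tests (half-life within 10% of ln 2/kp; residual
  < 0.5° after 30 s under a 2 °/s bias, and a nonzero plateau when
  ki = 0, demonstrating the integral term's role).
* **Initialisation** from the first sample's accelerometer inclination,
  not zero, so trials that begin lying or seated start from the correct
  posture.
* **Gimbal guard:** tan θ is clamped at |θ| = 89° and the state flagged;
  the pitch estimate itself is clamped inside (−90°, 90°). Backward and
  lateral falls approach the singularity. A consequence worth knowing:
  near |θ| ≈ 90° the roll angle is intrinsically unobservable (gravity
  lies along x and the tanθ term amplifies any y/z gyro bias), so roll
  accuracy claims are only meaningful away from gimbal lock.
* **Anti-windup:** the integral accumulators are clamped to ±20°. During
  free fall the accelerometer direction is meaningless; without the
  clamp the integrators can charge arbitrarily during the descent.
* **Wiring variants.** Whether the PI correction enters before or after
  the Euler-rate mapping is not uniquely determined by the block diagram
  this design follows; the exact inverse-mapped "pre" correction is
  algebraically identical to the "post" form, so the implemented `pre`
  option is the other plausible reading (corrections added to the raw
  body x/y rates). Both agree at small angles (tested); `post` is the
  default. An optional accelerometer gate (skip correction when
  a_SVM ∉ [0.5, 1.5] g) is provided and off by default — with kp = 1 the
  correction bandwidth is low enough that impact transients contribute
  little.

## Detector

Four thresholds: |roll| > 28°, pitch > 45° (signed, backward positive —
forward falls are out of scope by design, so the absolute value of
pitch is deliberately not used; roll is two-sided because lateral falls
occur to either side), ω_SVM > 47.3 °/s, and a_SVM **below** 0.82 g.
The below-threshold acceleration test encodes the free-fall dip: during
slow lying the vertical angle reaches ~90° exactly as in a fall, but
the body remains supported and a_SVM stays near 1 g.

The three condition groups need not hold at the same sample: each must
hold somewhere within a trailing 100 ms coincidence window
(`window_s`; 0 forces same-sample coincidence). This window reading is
one consistent interpretation of the decision flow and is isolated in
configuration; the streaming implementation is verified sample-exact
against a brute-force window re-scan on randomized trials. Detection
latches: one event per trial, as an airbag fires once.

`sweep_thresholds` reproduces the operating-point selection procedure:
evaluate a threshold grid and pick the point maximising specificity
subject to 100% sensitivity (ties resolved toward the smallest a_SVM
threshold, then the smallest angle thresholds).

## Evaluation

Per-trial confusion counts with the pre-impact rule: when the impact
time is known (video ground truth, or the simulator), a detection after
impact is scored FN — a post-impact airbag protects nothing. When
impact times are unknown (e.g. public datasets without video), any
detection on a fall trial counts as TP. Undefined metrics (zero
denominators) are reported as undefined, never as 0. Percentages are
displayed to 2 decimals. The per-activity false-positive table takes
its denominators from the data, never from an assumed design.

## Synthetic data generator

The generator renders declarative motion scripts into IMU trials via
the exact inverse of the estimator's kinematics: scripted roll/pitch
keyframes (shape-preserving PCHIP interpolation, so truth angles are
differentiable, plus analytically differentiated enveloped sinusoids
for gait sway) give Euler rates, which are inverted (zero yaw rate)
into body rates; gravity is projected into the body frame as
(sinθ, sinφ cosθ, cosφ cosθ).

Non-gravitational acceleration is realised mainly as a positive scalar
**support factor** multiplying body gravity: 1 while supported, dipping
to 0.3–0.5 during fall descents and gait flight phases, spiking above
2 g at impacts and landings. Because a positive scalar preserves the
acceleration direction, the accelerometer inclination of a noise-free
trial equals the scripted truth exactly — which is what makes the
suite a clean parameter-recovery oracle for the orientation filter.
Additive body-frame oscillations are also supported for morphologies
the scalar form cannot express.

Sensor imperfections: white noise (defaults σ_acc = 0.02 g,
σ_gyro = 0.5 °/s) and a constant per-trial gyro bias drawn uniformly
from ±1 °/s per axis — typical MEMS figures after coarse calibration.
Accelerometer and gyro noise use independent sub-streams of the trial
seed, so changing one never perturbs the other.

The standard suite mirrors the study design: every virtual subject
performs 14 ADLs and 6 fall types, 3 repetitions each, with per-trial
jitter; per-trial generators derive from (master seed, subject,
activity, repetition), so suites are byte-reproducible and subsets
regenerable. Script morphology choices (all editable in
`activity_scripts.SCRIPT_PARAMS`): fall descents 0.4–0.8 s with the
free-fall dip ending at the scripted impact; lying down over ~4 s with
a_SVM within [0.9, 1.1] g and ω_SVM below threshold; highly dynamic
ADLs (jogging, running in place, jumping, quick sits, collapse,
stumble) exceed 2 g peak raw a_SVM while less-dynamic ones stay below
2 g; forward leans use negative pitch. The known false-positive
mechanisms are scripted deliberately with jittered amplitudes that
straddle the thresholds: jogging curve-section roll (8–27° plus sway)
against the 28° threshold, and quick-sit pitch overshoot against 45° —
so a realistic minority (~3–4%) of highly dynamic ADL trials trip the
detector, concentrated in the same activities that cause trouble in
real data.

**What passing tests show — and don't.** The suite demonstrates
internal consistency: the estimator recovers the generator's truth, the
detector separates scripted falls from scripted ADLs at the published
thresholds with 100% sensitivity and ≥95% specificity, every detected
fall precedes its impact, and slow lying never triggers. It does not
validate the thresholds on human kinematics: script parameters are
plausible, not fitted to any recording (the original trials exist only
as published figures), there is no biomechanical segment model, no
contact dynamics, no soft-tissue or clothing artifacts, and subject
variability is simple parameter jitter. Likewise the suite's lead times
(~90–330 ms depending on fall type, mean ≈ 220 ms) are properties of
the scripted descent durations, not reproductions of any experimental
lead-time measurement, which would require the original
video-synchronised recordings.

## Problem sizes and numerics

End-to-end checks use 30 virtual subjects (1800 trials, ≈ 21 minutes of
signal), randomized detector-oracle comparisons use 50 trials and
monotonicity checks 100; these sizes give stable percentages (binomial
SE on specificity ≈ 0.5% at n = 1260 ADLs) while keeping the whole
suite fast. Determinism: all randomness flows from numpy SeedSequence
spawning; identical seeds give byte-identical CSV output. Degenerate
inputs are rejected loudly (non-finite samples, non-monotone or
non-uniform timestamps, zero accelerometer vectors, cutoffs at or above
Nyquist, series shorter than the filter warm-up).

## Known limitations

* Euler-angle orientation only (no yaw, no magnetometer, no
  quaternions in the public API); roll is unobservable at |pitch| ≈ 90°.
* The SisFall axis map is deployment-dependent; the shipped default is
  a documented guess and results depend on it. Public-dataset
  evaluation is an optional external-data path, not part of the test
  gates, because the preprocessing used in published comparisons
  (subject selection, axis mapping, resampling) is not specified.
* Forward falls and vertical-velocity features are out of scope.
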