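"""Synthetic IMU trial generator.

Each trial is scripted as a roll/pitch trajectory (keyframes plus
optional enveloped angular oscillations) and an acceleration profile.
The forward model is the exact inverse of the estimator's kinematics:

* the accelerometer channel is body-frame gravity, obtained by
  projecting the world vertical through the scripted roll/pitch,
  scaled by a positive "support factor" s(t) (1 while supported,
  dipping toward 0 in free fall, spiking above 2 at impact), plus any
  additive body-frame oscillations and Gaussian noise;
* the gyro channel is the exact body rates obtained by inverting the
  Euler-rate kinematic map from the scripted angle derivatives (zero
  yaw rate), plus a constant per-trial bias and Gaussian noise.

Because the scalar support factor preserves the acceleration
*direction*, the accelerometer inclination of a noise-free trial equals
the scripted angles exactly, which makes the generator a clean
parameter-recovery oracle for the orientation filter.

Scripts imitate signal morphology only: there is no body-segment model
and no contact dynamics.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .activities import ADL_ACTIVITIES, FALL_ACTIVITIES
from .evaluation import TrialLabel
from .signals import ImuSeries

__all__ = [
    "AngularOscillation",
    "LinearOscillation",
    "SupportOscillation",
    "MotionScript",
    "NoiseModel",
    "SyntheticTrial",
    "synthesize",
    "standard_suite",
    "PITCH_SCRIPT_LIMIT_DEG",
]

#: scripted pitch is clamped here to stay clear of the kinematic singularity
PITCH_SCRIPT_LIMIT_DEG = 89.5


@dataclasses.dataclass(frozen=True)
class AngularOscillation:
    """Sinusoidal roll or pitch component with a raised-cosine on/off ramp.

    Consistent by construction: it contributes both to the true angle
    trajectory and (through its analytic derivative) to the body rates.
    """

    axis: str  # "roll" | "pitch"
    amp_deg: float
    freq_hz: float
    t0: float
    t1: float
    phase: float = 0.0
    ramp_s: float = 0.3

    def __post_init__(self) -> None:
        if self.axis not in ("roll", "pitch"):
            raise ValueError("axis must be 'roll' or 'pitch'")
        if self.t1 <= self.t0:
            raise ValueError("t1 must exceed t0")


@dataclasses.dataclass(frozen=True)
class SupportOscillation:
    """Sinusoidal modulation of the support factor (gait loading cycles).

    Being a positive scalar on gravity it changes the acceleration SVM
    without changing its direction.
    """

    amp: float
    freq_hz: float
    t0: float
    t1: float
    phase: float = 0.0
    ramp_s: float = 0.3


@dataclasses.dataclass(frozen=True)
class LinearOscillation:
    """Additive body-frame non-gravitational acceleration component (g)."""

    axis: int  # 0=x, 1=y, 2=z
    amp_g: float
    freq_hz: float
    t0: float
    t1: float
    phase: float = 0.0
    ramp_s: float = 0.3


@dataclasses.dataclass
class MotionScript:
    """Declarative description of one activity trial.

    keyframes : (t, roll_deg, pitch_deg) control points, strictly
        increasing times inside [0, duration_s]; interpolated with a
        shape-preserving cubic (``interp='smooth'``) or linearly.
    support : optional (t, s) control points for the gravity support
        factor (free-fall dips and impact spikes live here).
    t_impact : ground-truth collision time; required for falls, and the
        impact spike is scripted to occur there.
    """

    name: str
    is_fall: bool
    duration_s: float
    keyframes: Sequence[tuple[float, float, float]]
    interp: str = "smooth"
    support: Optional[Sequence[tuple[float, float]]] = None
    ang_osc: Sequence[AngularOscillation] = ()
    sup_osc: Sequence[SupportOscillation] = ()
    lin_osc: Sequence[LinearOscillation] = ()
    t_impact: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interp not in ("smooth", "linear"):
            raise ValueError("interp must be 'smooth' or 'linear'")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        times = [k[0] for k in self.keyframes]
        if len(times) < 2:
            raise ValueError("need at least two keyframes")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"keyframe times must be strictly increasing: {self.name}")
        if times[0] < 0 or times[-1] > self.duration_s + 1e-9:
            raise ValueError("keyframes must lie within [0, duration_s]")
        if self.is_fall:
            if self.t_impact is None:
                raise ValueError(f"fall script {self.name!r} must define t_impact")
            if not 0 < self.t_impact < self.duration_s:
                raise ValueError("t_impact must lie inside the trial")
        if self.support is not None:
            st = [p[0] for p in self.support]
            if any(b <= a for a, b in zip(st, st[1:])):
                raise ValueError("support times must be strictly increasing")


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Sensor imperfection model: white noise plus constant gyro bias.

    Identical seed implies an identical trial.  Accelerometer and gyro
    noise come from independent sub-streams of the seed, so changing
    one sigma never perturbs the other channel.
    """

    accel_sigma: float = 0.02  # g
    gyro_sigma: float = 0.5  # deg/s
    gyro_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)  # deg/s per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_sigma < 0 or self.gyro_sigma < 0:
            raise ValueError("noise sigmas must be nonnegative")


@dataclasses.dataclass
class SyntheticTrial:
    """A generated trial: signals, label, and ground-truth trajectory."""

    series: ImuSeries
    label: TrialLabel
    truth_roll: np.ndarray
    truth_pitch: np.ndarray
    script: MotionScript

    @property
    def t_impact(self) -> Optional[float]:
        return self.label.t_impact


def _envelope(t: np.ndarray, t0: float, t1: float, ramp: float):
    """Raised-cosine on/off window on [t0, t1]; returns (env, d_env/dt)."""
    r = min(ramp, (t1 - t0) / 2.0)
    env = np.zeros_like(t)
    denv = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    if r <= 0:
        env[inside] = 1.0
        return env, denv
    up = inside & (t < t0 + r)
    down = inside & (t > t1 - r)
    mid = inside & ~up & ~down
    env[mid] = 1.0
    x = (t[up] - t0) / r
    env[up] = 0.5 * (1.0 - np.cos(np.pi * x))
    denv[up] = (np.pi / (2.0 * r)) * np.sin(np.pi * x)
    x = (t1 - t[down]) / r
    env[down] = 0.5 * (1.0 - np.cos(np.pi * x))
    denv[down] = -(np.pi / (2.0 * r)) * np.sin(np.pi * x)
    return env, denv


def _eval_keyframes(t: np.ndarray, times, values, interp: str):
    """Interpolate keyframes; returns (value, d_value/dt) on t."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interp == "smooth":
        f = PchipInterpolator(times, values, extrapolate=True)
        return f(t), f.derivative()(t)
    v = np.interp(t, times, values)
    return v, np.gradient(v, t)


def _angle_trajectory(script: MotionScript, t: np.ndarray):
    times = [k[0] for k in script.keyframes]
    roll, roll_rate = _eval_keyframes(t, times, [k[1] for k in script.keyframes], script.interp)
    pitch, pitch_rate = _eval_keyframes(t, times, [k[2] for k in script.keyframes], script.interp)
    for osc in script.ang_osc:
        env, denv = _envelope(t, osc.t0, osc.t1, osc.ramp_s)
        w = 2.0 * math.pi * osc.freq_hz
        arg = w * (t - osc.t0) + osc.phase
        val = osc.amp_deg * env * np.sin(arg)
        dval = osc.amp_deg * (denv * np.sin(arg) + env * w * np.cos(arg))
        if osc.axis == "roll":
            roll, roll_rate = roll + val, roll_rate + dval
        else:
            pitch, pitch_rate = pitch + val, pitch_rate + dval
    if np.any(np.abs(pitch) > PITCH_SCRIPT_LIMIT_DEG):
        warnings.warn(
            f"script {script.name!r}: pitch clamped to +-{PITCH_SCRIPT_LIMIT_DEG} deg "
            "(kinematic singularity)",
            stacklevel=3,
        )
        pitch = np.clip(pitch, -PITCH_SCRIPT_LIMIT_DEG, PITCH_SCRIPT_LIMIT_DEG)
    return roll, pitch, roll_rate, pitch_rate


def _support_factor(script: MotionScript, t: np.ndarray) -> np.ndarray:
    if script.support is not None:
        times = [p[0] for p in script.support]
        vals = [p[1] for p in script.support]
        # extend to the trial boundaries holding the end values
        if times[0] > 0:
            times, vals = [0.0] + times, [vals[0]] + vals
        if times[-1] < script.duration_s:
            times, vals = times + [script.duration_s], vals + [vals[-1]]
        s = PchipInterpolator(times, vals)(t)
    else:
        s = np.ones_like(t)
    for osc in script.sup_osc:
        env, _ = _envelope(t, osc.t0, osc.t1, osc.ramp_s)
        s = s + osc.amp * env * np.sin(2.0 * math.pi * osc.freq_hz * (t - osc.t0) + osc.phase)
    # support is a magnitude: keep it positive so the direction is preserved
    return np.clip(s, 0.05, None)


def synthesize(
    script: MotionScript,
    noise: NoiseModel = NoiseModel(),
    rate_hz: float = 100.0,
    trial_id: Optional[str] = None,
) -> SyntheticTrial:
    """Render a motion script into a sampled IMU trial."""
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    n = int(round(script.duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz

    roll, pitch, roll_rate, pitch_rate = _angle_trajectory(script, t)
    phi = np.radians(roll)
    th = np.radians(pitch)

    # body rates from Euler rates, zero yaw rate (inverse kinematic map)
    gx = roll_rate
    gy = np.cos(phi) * pitch_rate
    gz = -np.sin(phi) * pitch_rate

    s = _support_factor(script, t)
    acc = np.column_stack(
        [np.sin(th), np.sin(phi) * np.cos(th), np.cos(phi) * np.cos(th)]
    ) * s[:, None]
    for osc in script.lin_osc:
        env, _ = _envelope(t, osc.t0, osc.t1, osc.ramp_s)
        acc[:, osc.axis] += osc.amp_g * env * np.sin(
            2.0 * math.pi * osc.freq_hz * (t - osc.t0) + osc.phase
        )
    gyr = np.column_stack([gx, gy, gz])

    ss = np.random.SeedSequence(noise.seed)
    acc_child, gyr_child = ss.spawn(2)
    if noise.accel_sigma > 0:
        acc = acc + np.random.default_rng(acc_child).normal(0.0, noise.accel_sigma, (n, 3))
    if noise.gyro_sigma > 0:
        gyr = gyr + np.random.default_rng(gyr_child).normal(0.0, noise.gyro_sigma, (n, 3))
    gyr = gyr + np.asarray(noise.gyro_bias, float)

    label = TrialLabel(
        trial_id=trial_id or script.name,
        activity=script.name,
        is_fall=script.is_fall,
        t_impact=script.t_impact,
    )
    return SyntheticTrial(
        series=ImuSeries(t, acc, gyr, rate_hz),
        label=label,
        truth_roll=roll,
        truth_pitch=pitch,
        script=script,
    )


def standard_suite(
    n_subjects: int,
    seed: int,
    rate_hz: float = 100.0,
    repetitions: int = 3,
    noise: Optional[NoiseModel] = None,
) -> list[SyntheticTrial]:
    """The standard study design: every virtual subject performs the 14
    ADLs and 6 falls, ``repetitions`` times each, with per-trial random
    timing/amplitude jitter.

    One seeded generator per trial is derived from (master seed,
    subject, activity, repetition), so suites are reproducible and any
    subset can be regenerated independently.  ``noise`` overrides the
    default sensor model (its per-trial seed and gyro bias are still
    drawn from the trial stream).
    """
    from .activity_scripts import make_script  # deferred: scripts import this module's types

    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = NoiseModel() if noise is None else noise
    activities = list(ADL_ACTIVITIES) + list(FALL_ACTIVITIES)
    trials = []
    for subj in range(n_subjects):
        for a_idx, activity in enumerate(activities):
            for rep in range(repetitions):
                ss = np.random.SeedSequence([int(seed), subj, a_idx, rep])
                rng = np.random.default_rng(ss)
                script = make_script(activity, rng)
                bias = tuple(rng.uniform(-1.0, 1.0, 3)) if base.gyro_sigma > 0 or base.accel_sigma > 0 else (0.0, 0.0, 0.0)
                nm = dataclasses.replace(
                    base,
                    gyro_bias=bias if base.gyro_bias == (0.0, 0.0, 0.0) else base.gyro_bias,
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                )
                trial_id = f"S{subj:02d}_{activity}_r{rep}"
                trials.append(synthesize(script, nm, rate_hz, trial_id=trial_id))
    return trials
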