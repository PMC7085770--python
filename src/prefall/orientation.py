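"""Vertical-angle estimation: gyro/accelerometer fusion with a PI controller.

Roll and pitch are the body's tilt in the frontal and sagittal planes,
in degrees, with backward lean defined as *positive* pitch.  Two
independent measurements exist:

* integrating the body angular rates through the Euler-rate kinematic
  map (low noise short-term, but drifts with gyro bias), and
* the accelerometer inclination angles (drift-free, but corrupted by
  any non-gravitational acceleration, e.g. impacts).

The complementary filter integrates the gyro path and continuously
steers it toward the accelerometer angles through a proportional-
integral feedback on their discrepancy.  The integral term learns and
cancels constant gyro bias; the proportional term sets the crossover
between trusting the gyro (fast) and the accelerometer (slow).

Numerical scheme: explicit Euler at the sample interval, matching a
real-time sequential update at 100 Hz.  The Euler-rate map has a
singularity at |pitch| = 90 deg; tan(pitch) is clamped at 89 deg (the
"gimbal guard") and the state is flagged when the guard engages.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .signals import ImuSample, ImuSeries

__all__ = [
    "FilterGains",
    "OrientationState",
    "OrientationTrack",
    "UndefinedInclinationError",
    "accel_angles",
    "euler_rates",
    "fuse_step",
    "estimate_series",
    "PITCH_GUARD_DEG",
]

log = logging.getLogger(__name__)

PITCH_GUARD_DEG = 89.0
#: hard clamp on the pitch estimate itself, keeping it inside (-90, 90)
_PITCH_CLAMP_DEG = 89.9


class UndefinedInclinationError(ValueError):
    """Accelerometer inclination is undefined for a zero acceleration vector."""


@dataclasses.dataclass(frozen=True)
class FilterGains:
    """PI gains of the complementary filter.

    kp is dimensionless (1/s on the angle error); ki has units 1/s^2.
    The defaults (kp=1.0, ki=0.1) give a ~1 s accelerometer crossover
    and full rejection of constant gyro bias within ~30 s.
    """

    kp: float = 1.0
    ki: float = 0.1

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise ValueError("PI gains must be nonnegative")


@dataclasses.dataclass
class OrientationState:
    """Roll/pitch estimate plus the PI integral accumulators, all in degrees."""

    roll: float
    pitch: float
    i_roll: float = 0.0
    i_pitch: float = 0.0
    t: float = 0.0
    gimbal_flagged: bool = False


@dataclasses.dataclass
class OrientationTrack:
    """Per-sample orientation states of a whole trial, stored as arrays."""

    t: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    i_roll: np.ndarray
    i_pitch: np.ndarray
    gimbal_flagged: np.ndarray

    def __len__(self) -> int:
        return self.t.shape[0]

    def __getitem__(self, i: int) -> OrientationState:
        return OrientationState(
            roll=float(self.roll[i]),
            pitch=float(self.pitch[i]),
            i_roll=float(self.i_roll[i]),
            i_pitch=float(self.i_pitch[i]),
            t=float(self.t[i]),
            gimbal_flagged=bool(self.gimbal_flagged[i]),
        )


def accel_angles(ax, ay, az):
    """Inclination (roll, pitch) in degrees from one accelerometer vector.

    roll  = atan( ay / sqrt(ax^2 + az^2) )
    pitch = atan( ax / sqrt(ay^2 + az^2) )

    Valid whenever the accelerometer reads pure gravity; undefined for a
    zero vector.  Accepts scalars or arrays.
    """
    ax, ay, az = np.asarray(ax, float), np.asarray(ay, float), np.asarray(az, float)
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    if np.any(norm == 0.0):
        raise UndefinedInclinationError("zero acceleration vector has no inclination")
    roll = np.degrees(np.arctan2(ay, np.hypot(ax, az)))
    pitch = np.degrees(np.arctan2(ax, np.hypot(ay, az)))
    if roll.ndim == 0:
        return float(roll), float(pitch)
    return roll, pitch


def euler_rates(gx: float, gy: float, gz: float, roll: float, pitch: float):
    """Map body angular rates (deg/s) to roll/pitch Euler-angle rates.

    roll_rate  = gx + sin(roll) tan(pitch) gy + cos(roll) tan(pitch) gz
    pitch_rate = cos(roll) gy - sin(roll) gz

    tan(pitch) is clamped at |pitch| = PITCH_GUARD_DEG to avoid the
    gimbal singularity (backward and lateral falls approach 90 deg).
    """
    pc = max(-PITCH_GUARD_DEG, min(PITCH_GUARD_DEG, pitch))
    tp = math.tan(math.radians(pc))
    sr = math.sin(math.radians(roll))
    cr = math.cos(math.radians(roll))
    return gx + sr * tp * gy + cr * tp * gz, cr * gy - sr * gz


def _wrap_roll(roll: float) -> float:
    if roll > 180.0:
        return roll - 360.0
    if roll < -180.0:
        return roll + 360.0
    return roll


def fuse_step(
    state: OrientationState,
    sample: ImuSample,
    gains: FilterGains,
    dt: float,
    *,
    i_limit_deg: float = 20.0,
    correction: str = "post",
    accel_gate: bool = False,
    gate_band: tuple[float, float] = (0.5, 1.5),
) -> OrientationState:
    """Advance the orientation estimate by one sample.

    Per axis: error e = accelerometer angle - current estimate; the
    integral accumulator gains ki*e*dt (clamped to +-i_limit_deg against
    windup during free fall, when the accelerometer angle is
    meaningless); the corrected rate is the Euler-mapped gyro rate plus
    kp*e plus the accumulator; the angle advances by the corrected rate
    times dt.

    ``correction="post"`` (default) applies the PI terms after the
    Euler-rate mapping; ``"pre"`` adds them to the raw body x/y rates
    before the mapping.  ``accel_gate`` optionally disables the
    accelerometer correction while the acceleration SVM is outside
    ``gate_band`` (high dynamics), freezing the integrators.

    A non-finite sample leaves the estimate unchanged (logged).
    """
    if correction not in ("post", "pre"):
        raise ValueError("correction must be 'post' or 'pre'")
    if dt <= 0:
        raise ValueError("dt must be positive")
    vals = (sample.ax, sample.ay, sample.az, sample.gx, sample.gy, sample.gz)
    if not all(math.isfinite(v) for v in vals):
        log.warning("non-finite sample at t=%s ignored", sample.t)
        return dataclasses.replace(state, t=state.t + dt)

    anorm = math.sqrt(sample.ax**2 + sample.ay**2 + sample.az**2)
    use_accel = anorm > 0.0 and not (accel_gate and not gate_band[0] <= anorm <= gate_band[1])
    if use_accel:
        roll_a, pitch_a = accel_angles(sample.ax, sample.ay, sample.az)
        e_roll = roll_a - state.roll
        e_pitch = pitch_a - state.pitch
        i_roll = _clip(state.i_roll + gains.ki * e_roll * dt, i_limit_deg)
        i_pitch = _clip(state.i_pitch + gains.ki * e_pitch * dt, i_limit_deg)
    else:
        e_roll = e_pitch = 0.0
        i_roll, i_pitch = state.i_roll, state.i_pitch

    if correction == "pre":
        gx = sample.gx + gains.kp * e_roll + i_roll
        gy = sample.gy + gains.kp * e_pitch + i_pitch
        rr, pr = euler_rates(gx, gy, sample.gz, state.roll, state.pitch)
        roll = state.roll + rr * dt
        pitch = state.pitch + pr * dt
    else:
        rr, pr = euler_rates(sample.gx, sample.gy, sample.gz, state.roll, state.pitch)
        roll = state.roll + (rr + gains.kp * e_roll + i_roll) * dt
        pitch = state.pitch + (pr + gains.kp * e_pitch + i_pitch) * dt

    roll = _wrap_roll(roll)
    pitch = _clip(pitch, _PITCH_CLAMP_DEG)
    flagged = abs(state.pitch) >= PITCH_GUARD_DEG
    return OrientationState(roll, pitch, i_roll, i_pitch, state.t + dt, flagged)


def _clip(x: float, lim: float) -> float:
    return lim if x > lim else (-lim if x < -lim else x)


def estimate_series(
    series: ImuSeries,
    gains: FilterGains = FilterGains(),
    *,
    i_limit_deg: float = 20.0,
    correction: str = "post",
    accel_gate: bool = False,
    gate_band: tuple[float, float] = (0.5, 1.5),
    initial: OrientationState | None = None,
) -> OrientationTrack:
    """Run the complementary filter over a whole trial.

    Returns one state per sample.  The initial angles are taken from the
    accelerometer inclination of the first sample (not zero), so trials
    that start in non-upright postures are handled correctly.  Only
    sample *intervals* matter; adding a constant to all timestamps does
    not change the output.
    """
    if correction not in ("post", "pre"):
        raise ValueError("correction must be 'post' or 'pre'")
    n = series.n
    dt = series.dt
    kp, ki = gains.kp, gains.ki
    ilim = i_limit_deg
    lo, hi = gate_band
    pre = correction == "pre"

    ax_, ay_, az_ = (series.acc[:, j].tolist() for j in range(3))
    gx_, gy_, gz_ = (series.gyr[:, j].tolist() for j in range(3))

    if initial is not None:
        roll, pitch = initial.roll, initial.pitch
        ir, ip = initial.i_roll, initial.i_pitch
    else:
        roll, pitch = accel_angles(ax_[0], ay_[0], az_[0])
        ir = ip = 0.0

    out_roll = np.empty(n)
    out_pitch = np.empty(n)
    out_ir = np.empty(n)
    out_ip = np.empty(n)
    out_flag = np.zeros(n, dtype=bool)
    out_roll[0], out_pitch[0], out_ir[0], out_ip[0] = roll, pitch, ir, ip

    rad = math.radians
    deg = math.degrees
    atan2, hypot, sqrt = math.atan2, math.hypot, math.sqrt
    sin, cos, tan = math.sin, math.cos, math.tan
    guard = PITCH_GUARD_DEG

    for i in range(1, n):
        axi, ayi, azi = ax_[i], ay_[i], az_[i]
        gxi, gyi, gzi = gx_[i], gy_[i], gz_[i]
        anorm = sqrt(axi * axi + ayi * ayi + azi * azi)
        if anorm > 0.0 and not (accel_gate and not lo <= anorm <= hi):
            e_r = deg(atan2(ayi, hypot(axi, azi))) - roll
            e_p = deg(atan2(axi, hypot(ayi, azi))) - pitch
            ir += ki * e_r * dt
            ip += ki * e_p * dt
            if ir > ilim:
                ir = ilim
            elif ir < -ilim:
                ir = -ilim
            if ip > ilim:
                ip = ilim
            elif ip < -ilim:
                ip = -ilim
        else:
            e_r = e_p = 0.0

        pc = pitch
        flagged = False
        if pc > guard:
            pc = guard
            flagged = True
        elif pc < -guard:
            pc = -guard
            flagged = True
        tp = tan(rad(pc))
        sr = sin(rad(roll))
        cr = cos(rad(roll))
        if pre:
            gxc = gxi + kp * e_r + ir
            gyc = gyi + kp * e_p + ip
            roll += (gxc + sr * tp * gyc + cr * tp * gzi) * dt
            pitch += (cr * gyc - sr * gzi) * dt
        else:
            roll += (gxi + sr * tp * gyi + cr * tp * gzi + kp * e_r + ir) * dt
            pitch += (cr * gyi - sr * gzi + kp * e_p + ip) * dt

        if roll > 180.0:
            roll -= 360.0
        elif roll < -180.0:
            roll += 360.0
        if pitch > _PITCH_CLAMP_DEG:
            pitch = _PITCH_CLAMP_DEG
        elif pitch < -_PITCH_CLAMP_DEG:
            pitch = -_PITCH_CLAMP_DEG

        out_roll[i], out_pitch[i], out_ir[i], out_ip[i] = roll, pitch, ir, ip
        out_flag[i] = flagged

    return OrientationTrack(series.t.copy(), out_roll, out_pitch, out_ir, out_ip, out_flag)
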