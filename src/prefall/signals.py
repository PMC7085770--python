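"""IMU data containers, low-pass filtering, and sum-vector-magnitude features.

The sensor model is a waist-worn 6-axis IMU sampled nominally at 100 Hz:
three acceleration channels in units of g and three angular-rate channels
in degrees per second.  Axis convention (fixed throughout the package):
x anteroposterior, y mediolateral, z superoinferior, so quiet standing
reads approximately (0, 0, 1) g.

SVM here means *sum vector magnitude* — the Euclidean norm of a 3-axis
sample — not a support vector machine.  The acceleration SVM (aSVM) and
angular-velocity SVM (wSVM) are the two scalar features the detector
thresholds, alongside the roll/pitch vertical angles estimated in
:mod:`prefall.orientation`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SignalError",
    "SeriesTooShortError",
    "ImuSample",
    "ImuSeries",
    "acc_svm",
    "gyro_svm",
    "asvm",
    "wsvm",
    "lowpass",
]


class SignalError(ValueError):
    """Invalid signal data or filter parameters."""


class SeriesTooShortError(SignalError):
    """Series too short for the requested filtering operation."""


@dataclasses.dataclass(frozen=True)
class ImuSample:
    """One time-stamped 6-axis sample: accelerations in g, rates in deg/s."""

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float

    def __post_init__(self) -> None:
        for name in ("t", "ax", "ay", "az", "gx", "gy", "gz"):
            if not math.isfinite(getattr(self, name)):
                raise SignalError(f"non-finite value in ImuSample field {name!r}")


@dataclasses.dataclass
class ImuSeries:
    """Uniformly sampled 6-axis inertial series.

    Parameters
    ----------
    t : (n,) array of timestamps in seconds, strictly increasing and uniform
        to within 1 % of the nominal sample interval ``1 / rate_hz``.
    acc : (n, 3) array of accelerations in g, columns x/y/z.
    gyr : (n, 3) array of angular velocities in deg/s, columns x/y/z.
    rate_hz : nominal sampling rate (100 Hz for the wearable prototype,
        200 Hz for SisFall recordings).
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        n = self.t.shape[0]
        if n < 2:
            raise SignalError("ImuSeries needs at least 2 samples")
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise SignalError(
                f"shape mismatch: t has {n} samples, acc {self.acc.shape}, gyr {self.gyr.shape}"
            )
        if not (
            np.all(np.isfinite(self.t))
            and np.all(np.isfinite(self.acc))
            and np.all(np.isfinite(self.gyr))
        ):
            raise SignalError("ImuSeries contains non-finite values")
        if self.rate_hz <= 0:
            raise SignalError("rate_hz must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise SignalError("timestamps must be strictly increasing")
        nominal = 1.0 / self.rate_hz
        if np.max(np.abs(dt - nominal)) > 0.01 * nominal:
            raise SignalError(
                "timestamps not uniform to within 1% of the nominal interval "
                f"(nominal {nominal:.6g} s)"
            )

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.n

    def sample(self, i: int) -> ImuSample:
        return ImuSample(
            float(self.t[i]),
            *(float(v) for v in self.acc[i]),
            *(float(v) for v in self.gyr[i]),
        )

    def __iter__(self) -> Iterator[ImuSample]:
        return (self.sample(i) for i in range(self.n))


def acc_svm(ax, ay, az):
    """Acceleration sum vector magnitude sqrt(ax^2 + ay^2 + az^2), in g.

    Accepts scalars or broadcastable arrays.
    """
    ax, ay, az = np.asarray(ax, float), np.asarray(ay, float), np.asarray(az, float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise SignalError("acc_svm requires finite inputs")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def gyro_svm(gx, gy, gz):
    """Angular-velocity sum vector magnitude, in deg/s."""
    gx, gy, gz = np.asarray(gx, float), np.asarray(gy, float), np.asarray(gz, float)
    if not (np.all(np.isfinite(gx)) and np.all(np.isfinite(gy)) and np.all(np.isfinite(gz))):
        raise SignalError("gyro_svm requires finite inputs")
    out = np.sqrt(gx * gx + gy * gy + gz * gz)
    return float(out) if out.ndim == 0 else out


def asvm(series: ImuSeries) -> np.ndarray:
    """Per-sample acceleration SVM of a series."""
    return np.linalg.norm(series.acc, axis=1)


def wsvm(series: ImuSeries) -> np.ndarray:
    """Per-sample angular-velocity SVM of a series."""
    return np.linalg.norm(series.gyr, axis=1)


def lowpass(
    series: ImuSeries,
    cutoff_hz: float = 5.0,
    *,
    order: int = 2,
    zero_phase: bool = False,
) -> ImuSeries:
    """Low-pass filter all six channels of a series.

    The filter is a Butterworth of the given order.  By default it is
    applied causally (single pass), because a pre-impact trigger cannot
    look at future samples; ``zero_phase=True`` selects an offline
    forward-backward pass instead.  The causal filter is initialised at
    the steady-state response to the first sample, so a constant input
    passes through unchanged.

    Timestamps, length and sampling rate are preserved exactly.
    """
    nyq = series.rate_hz / 2.0
    if not 0.0 < cutoff_hz < nyq:
        raise SignalError(f"cutoff_hz must be in (0, {nyq}) for rate {series.rate_hz} Hz")
    min_len = 3 * (2 * order + 1)
    if series.n < min_len:
        raise SeriesTooShortError(
            f"series of {series.n} samples is shorter than the filter warm-up ({min_len})"
        )
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=series.rate_hz, output="sos")
    data = np.hstack([series.acc, series.gyr])
    if zero_phase:
        out = _sig.sosfiltfilt(sos, data, axis=0)
    else:
        zi = _sig.sosfilt_zi(sos)  # steady-state for unit step
        out = np.empty_like(data)
        for c in range(data.shape[1]):
            out[:, c], _ = _sig.sosfilt(sos, data[:, c], zi=zi * data[0, c])
    return ImuSeries(series.t.copy(), out[:, :3], out[:, 3:], series.rate_hz)
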