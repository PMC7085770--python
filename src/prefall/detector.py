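"""Four-threshold pre-impact fall decision logic.

A fall is called at the first time at which, within a short sliding
coincidence window, all three condition groups have each been met:

1. angle condition: |roll| above its threshold (lateral falls occur to
   either side) OR pitch above its threshold (pitch is signed with
   backward lean positive: forward falls are out of scope, so the
   absolute value of pitch is deliberately not used);
2. angular-velocity SVM above its threshold (fast rotation);
3. acceleration SVM *below* its threshold (the free-fall dip during
   descent — this is what separates a fall from slowly lying down,
   where the vertical angle also reaches ~90 deg but the body stays
   supported and the aSVM never drops).

Default thresholds: roll 28 deg, pitch 45 deg, wSVM 47.3 deg/s,
aSVM 0.82 g.  Detection latches: one event per trial (the airbag
fires once).  Features are computed on the low-pass-filtered series.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import TrialLabel, classify_trial
from .orientation import FilterGains, OrientationTrack, estimate_series
from .signals import ImuSeries, asvm, lowpass, wsvm

__all__ = [
    "DetectorConfig",
    "DetectionEvent",
    "TrialFeatures",
    "compute_features",
    "detect",
    "detect_features",
    "detect_trial",
    "sweep_thresholds",
    "SweepResult",
]


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """The four thresholds plus the coincidence window and warm-up.

    th_asvm : g, *below*-threshold free-fall condition (default 0.82)
    th_wsvm : deg/s (default 47.3)
    th_roll : deg, tested as |roll| (default 28)
    th_pitch : deg, signed, backward positive (default 45)
    window_s : sliding coincidence window; 0 forces same-sample
        coincidence of all three groups (default 0.10 s)
    warmup_s : initial span excluded from all conditions, covering the
        low-pass filter and orientation-estimate transients (default 0.5 s)
    """

    th_asvm: float = 0.82
    th_wsvm: float = 47.3
    th_roll: float = 28.0
    th_pitch: float = 45.0
    window_s: float = 0.10
    warmup_s: float = 0.5

    def __post_init__(self) -> None:
        if min(self.th_asvm, self.th_wsvm, self.th_roll, self.th_pitch) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.window_s < 0 or self.warmup_s < 0:
            raise ValueError("window_s and warmup_s must be nonnegative")


@dataclasses.dataclass(frozen=True)
class DetectionEvent:
    """A latched fall call: when it fired and what the features were."""

    t_detect: float
    index: int
    triggered_by: str  # "roll", "pitch" or "roll+pitch"
    asvm: float
    wsvm: float
    roll: float
    pitch: float


@dataclasses.dataclass
class TrialFeatures:
    """Precomputed per-sample detector features of one trial."""

    t: np.ndarray
    rate_hz: float
    asvm: np.ndarray
    wsvm: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray


def compute_features(
    series: ImuSeries,
    *,
    cutoff_hz: float = 5.0,
    zero_phase: bool = False,
    gains: FilterGains = FilterGains(),
    correction: str = "post",
    accel_gate: bool = False,
    i_limit_deg: float = 20.0,
) -> TrialFeatures:
    """Low-pass filter a raw trial and derive the detector features."""
    filt = lowpass(series, cutoff_hz, zero_phase=zero_phase)
    track = estimate_series(
        filt,
        gains,
        correction=correction,
        accel_gate=accel_gate,
        i_limit_deg=i_limit_deg,
    )
    return TrialFeatures(filt.t, filt.rate_hz, asvm(filt), wsvm(filt), track.roll, track.pitch)


def _window_any(mask: np.ndarray, w: int) -> np.ndarray:
    """mask ORed over the trailing window [i-w, i], vectorised O(n)."""
    n = mask.shape[0]
    idx = np.where(mask, np.arange(n), -1)
    last_true = np.maximum.accumulate(idx)
    return (last_true >= 0) & (last_true >= np.arange(n) - w)


def detect_features(feat: TrialFeatures, cfg: DetectorConfig = DetectorConfig()) -> Optional[DetectionEvent]:
    """Run the threshold logic on precomputed features."""
    warm = (feat.t - feat.t[0]) < cfg.warmup_s
    roll_c = (np.abs(feat.roll) > cfg.th_roll) & ~warm
    pitch_c = (feat.pitch > cfg.th_pitch) & ~warm
    angle_c = roll_c | pitch_c
    w_c = (feat.wsvm > cfg.th_wsvm) & ~warm
    a_c = (feat.asvm < cfg.th_asvm) & ~warm

    w = int(round(cfg.window_s * feat.rate_hz))
    ok = _window_any(angle_c, w) & _window_any(w_c, w) & _window_any(a_c, w)
    if not ok.any():
        return None
    i = int(np.argmax(ok))
    lo = max(0, i - w)
    roll_fired = bool(roll_c[lo : i + 1].any())
    pitch_fired = bool(pitch_c[lo : i + 1].any())
    trig = {(True, False): "roll", (False, True): "pitch", (True, True): "roll+pitch"}[
        (roll_fired, pitch_fired)
    ]
    return DetectionEvent(
        t_detect=float(feat.t[i]),
        index=i,
        triggered_by=trig,
        asvm=float(feat.asvm[i]),
        wsvm=float(feat.wsvm[i]),
        roll=float(feat.roll[i]),
        pitch=float(feat.pitch[i]),
    )


def detect(
    series: ImuSeries,
    angles: OrientationTrack,
    cfg: DetectorConfig = DetectorConfig(),
) -> Optional[DetectionEvent]:
    """Detect on an already low-pass-filtered series and its angle track.

    ``angles`` must be aligned 1:1 with ``series`` (same timestamps);
    misalignment is a contract error.  Returns the first latched event,
    or None.
    """
    if len(angles) != series.n or not np.allclose(angles.t, series.t):
        raise ValueError("angle track is not aligned 1:1 with the series")
    feat = TrialFeatures(series.t, series.rate_hz, asvm(series), wsvm(series), angles.roll, angles.pitch)
    return detect_features(feat, cfg)


def detect_trial(
    series: ImuSeries,
    cfg: DetectorConfig = DetectorConfig(),
    **feature_opts,
) -> Optional[DetectionEvent]:
    """Convenience pipeline: filter a *raw* trial, estimate angles, detect."""
    return detect_features(compute_features(series, **feature_opts), cfg)


@dataclasses.dataclass
class SweepResult:
    """Grid-search output: the full table and the selected operating point."""

    table: pd.DataFrame
    best: Optional[pd.Series]


def sweep_thresholds(
    trials: Sequence,
    grid: Mapping[str, Iterable[float]],
    *,
    base: DetectorConfig = DetectorConfig(),
    **feature_opts,
) -> SweepResult:
    """Grid-search the four thresholds over a labelled trial set.

    ``trials`` is a sequence of objects with ``label`` (TrialLabel) and
    ``series`` (raw ImuSeries) attributes — e.g. SyntheticTrial — or
    ``(label, series)`` tuples.  ``grid`` maps any of
    th_asvm/th_wsvm/th_roll/th_pitch to candidate values; omitted
    parameters stay at their ``base`` value.

    Every grid point is evaluated (features are computed once per
    trial).  The selected point maximises specificity subject to 100 %
    sensitivity, ties broken by the smallest aSVM threshold, then the
    smallest roll, pitch and wSVM thresholds.  ``best`` is None when no
    point reaches 100 % sensitivity.
    """
    keys = ("th_asvm", "th_wsvm", "th_roll", "th_pitch")
    unknown = set(grid) - set(keys)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    axes = []
    for k in keys:
        vals = list(grid.get(k, [getattr(base, k)]))
        if not vals:
            raise ValueError(f"empty grid for {k}")
        axes.append(vals)

    prepared: list[tuple[TrialLabel, TrialFeatures]] = []
    n_falls = n_adls = 0
    for tr in trials:
        label, series = (tr.label, tr.series) if hasattr(tr, "label") else tr
        prepared.append((label, compute_features(series, **feature_opts)))
        n_falls += label.is_fall
        n_adls += not label.is_fall
    if n_falls == 0 or n_adls == 0:
        raise ValueError("sweep needs at least one fall and one ADL trial")

    rows = []
    for ta, tw, tr_, tp in itertools.product(*axes):
        cfg = dataclasses.replace(base, th_asvm=ta, th_wsvm=tw, th_roll=tr_, th_pitch=tp)
        tpc = fpc = tnc = fnc = 0
        for label, feat in prepared:
            outcome = classify_trial(label, detect_features(feat, cfg))
            if outcome == "TP":
                tpc += 1
            elif outcome == "FP":
                fpc += 1
            elif outcome == "TN":
                tnc += 1
            else:
                fnc += 1
        rows.append(
            dict(
                th_asvm=ta,
                th_wsvm=tw,
                th_roll=tr_,
                th_pitch=tp,
                tp=tpc,
                fp=fpc,
                tn=tnc,
                fn=fnc,
                sensitivity=100.0 * tpc / (tpc + fnc),
                specificity=100.0 * tnc / (tnc + fpc),
            )
        )
    table = pd.DataFrame(rows)
    feasible = table[table["sensitivity"] == 100.0]
    best = None
    if not feasible.empty:
        ordered = feasible.sort_values(
            ["specificity", "th_asvm", "th_roll", "th_pitch", "th_wsvm"],
            ascending=[False, True, True, True, True],
        )
        best = ordered.iloc[0]
    return SweepResult(table=table, best=best)
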