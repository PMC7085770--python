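"""Trial-level scoring: confusion metrics, lead time, per-activity FP table.

A trial is one labelled recording.  A fall trial with a detection is a
true positive only if the call came *before* the ground impact (an
airbag fired after the collision is useless), when the impact time is
known; without ground-truth impact times (e.g. public datasets with no
video), any detection on a fall trial counts as a true positive.

Lead time = impact time - detection time, in milliseconds.  It must
exceed the airbag inflation time (~200 ms) to be protective.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .activities import ADL_ACTIVITIES, ALL_ACTIVITIES, FALL_ACTIVITIES

__all__ = [
    "TrialLabel",
    "ConfusionMetrics",
    "classify_trial",
    "metrics",
    "lead_time",
    "fp_table",
    "lead_time_table",
]

Outcome = str  # "TP" | "FP" | "TN" | "FN"


@dataclasses.dataclass(frozen=True)
class TrialLabel:
    """Ground truth for one trial.

    t_impact_s is the video-determined body-ground collision time; it is
    present only for fall trials with known ground truth.
    """

    trial_id: str
    activity: str
    is_fall: bool
    t_impact: Optional[float] = None

    def __post_init__(self) -> None:
        if self.activity in ALL_ACTIVITIES:
            if self.is_fall != (self.activity in FALL_ACTIVITIES):
                raise ValueError(
                    f"label {self.trial_id!r}: is_fall={self.is_fall} inconsistent "
                    f"with activity {self.activity!r}"
                )
        if self.t_impact is not None and not self.is_fall:
            raise ValueError(f"label {self.trial_id!r}: t_impact given for a non-fall trial")


def _t_detect(event) -> float:
    """Accept a DetectionEvent, anything with .t_detect, or a bare time."""
    if hasattr(event, "t_detect"):
        return float(event.t_detect)
    return float(event)


def classify_trial(label: TrialLabel, event) -> Outcome:
    """Score one trial as TP/FP/TN/FN.

    ``event`` is a detection (DetectionEvent or detection time in s) or
    None.  A fall detected after its known impact time is a miss (FN).
    """
    if label.is_fall:
        if event is None:
            return "FN"
        if label.t_impact is not None and _t_detect(event) > label.t_impact:
            return "FN"
        return "TP"
    return "FP" if event is not None else "TN"


@dataclasses.dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with the derived percentage metrics.

    sensitivity = TP/(TP+FN)*100, specificity = TN/(TN+FP)*100,
    accuracy = (TP+TN)/total*100.  A metric whose denominator is zero is
    None ("undefined"), never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def accuracy(self) -> Optional[float]:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else None

    @property
    def fp_rate(self) -> Optional[float]:
        """False-positive rate among ADL trials, % (100 - specificity)."""
        s = self.specificity
        return None if s is None else 100.0 - s

    def summary(self) -> str:
        def fmt(v: Optional[float]) -> str:
            return "undefined" if v is None else f"{v:.2f}%"

        return (
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} | "
            f"sensitivity {fmt(self.sensitivity)}, specificity {fmt(self.specificity)}, "
            f"accuracy {fmt(self.accuracy)}"
        )


def metrics(outcomes: Iterable[Outcome]) -> ConfusionMetrics:
    """Aggregate a multiset of TP/FP/TN/FN outcomes."""
    counts = Counter(outcomes)
    unknown = set(counts) - {"TP", "FP", "TN", "FN"}
    if unknown:
        raise ValueError(f"unknown outcomes: {sorted(unknown)}")
    if not counts:
        raise ValueError("metrics need at least one trial")
    return ConfusionMetrics(counts["TP"], counts["FP"], counts["TN"], counts["FN"])


def lead_time(event, t_impact: float) -> float:
    """Lead time in ms: (t_impact - t_detect) * 1000.  May be negative."""
    return (float(t_impact) - _t_detect(event)) * 1000.0


def fp_table(
    labels: Iterable[TrialLabel],
    events: Mapping[str, object],
) -> pd.DataFrame:
    """Per-ADL-activity false-positive counts, denominators from the data.

    ``events`` maps trial_id to a detection (or None).  Rows are indexed
    by activity with columns ``fp`` and ``n``, plus a ``total`` row.
    """
    labels = list(labels)
    per: dict[str, list[int]] = {}
    for lab in labels:
        if lab.is_fall:
            continue
        fp, n = per.setdefault(lab.activity, [0, 0])
        per[lab.activity][1] = n + 1
        if events.get(lab.trial_id) is not None:
            per[lab.activity][0] = fp + 1
    ordered = [a for a in ADL_ACTIVITIES if a in per] + sorted(set(per) - set(ADL_ACTIVITIES))
    rows = {a: per[a] for a in ordered}
    rows["total"] = [sum(v[0] for v in per.values()), sum(v[1] for v in per.values())]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["fp", "n"])


def lead_time_table(
    labels: Iterable[TrialLabel],
    events: Mapping[str, object],
) -> pd.DataFrame:
    """Mean +- SD lead time (ms) per fall type, over detected falls with
    known impact times."""
    per: dict[str, list[float]] = {}
    for lab in labels:
        if not lab.is_fall or lab.t_impact is None:
            continue
        ev = events.get(lab.trial_id)
        if ev is None:
            continue
        per.setdefault(lab.activity, []).append(lead_time(ev, lab.t_impact))
    ordered = [a for a in FALL_ACTIVITIES if a in per] + sorted(set(per) - set(FALL_ACTIVITIES))
    rows = {}
    for a in ordered:
        lt = np.asarray(per[a])
        rows[a] = [lt.mean(), lt.std(ddof=1) if lt.size > 1 else 0.0, lt.size]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["mean_ms", "sd_ms", "n"])
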