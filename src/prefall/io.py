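"""Readers and writers: trial CSV, labels CSV, SisFall text, YAML config.

Units are enforced at this boundary: everything inside the package is in
g and deg/s.  The trial CSV schema is

    t_s,ax_g,ay_g,az_g,gx_dps,gy_dps,gz_dps

one row per sample, UTF-8, ``.`` decimal separator.  SisFall recordings
are raw integer counts (13-bit accelerometer at +-16 g, 16-bit gyro at
+-2000 deg/s, 200 Hz) and are converted here; because the SisFall unit
was worn at the front of the waist with a different axis orientation,
an explicit axis map onto this package's x/y/z convention is required.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .detector import DetectorConfig
from .evaluation import TrialLabel
from .orientation import FilterGains, OrientationTrack
from .signals import ImuSeries, SignalError

__all__ = [
    "SchemaError",
    "SisFallFormatError",
    "TRIAL_COLUMNS",
    "read_trial_csv",
    "write_trial_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_angles_csv",
    "read_sisfall",
    "parse_axis_map",
    "DEFAULT_SISFALL_AXIS_MAP",
    "SISFALL_ACC_SCALE_G",
    "SISFALL_GYR_SCALE_DPS",
    "PipelineConfig",
    "load_config",
    "dump_config",
]

log = logging.getLogger(__name__)

TRIAL_COLUMNS = ("t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps")
LABEL_COLUMNS = ("trial_id", "activity", "is_fall", "t_impact_s")

#: raw count -> g: 13-bit ADC over a +-16 g span
SISFALL_ACC_SCALE_G = 2.0 * 16.0 / 2**13
#: raw count -> deg/s: 16-bit ADC over a +-2000 deg/s span
SISFALL_GYR_SCALE_DPS = 2.0 * 2000.0 / 2**16

#: Documented *guess* for mapping SisFall device axes onto this package's
#: convention (x anteroposterior, y mediolateral, z superoinferior, upright
#: az = +1 g).  Placement and orientation differ between deployments —
#: verify against a standing segment of your own data before trusting it.
DEFAULT_SISFALL_AXIS_MAP = {"x": "+z", "y": "+x", "z": "-y"}


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


class SisFallFormatError(ValueError):
    """A SisFall text file line could not be parsed."""


# --------------------------------------------------------------------------
# trial CSV

def write_trial_csv(series: ImuSeries, path) -> None:
    data = np.column_stack([series.t, series.acc, series.gyr])
    header = ",".join(TRIAL_COLUMNS)
    np.savetxt(path, data, fmt="%.8g", delimiter=",", header=header, comments="")


def read_trial_csv(path, rate_hz: Optional[float] = None) -> ImuSeries:
    """Read a trial CSV; column order is free, names are authoritative."""
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    t = df["t_s"].to_numpy(float)
    if t.size >= 2 and rate_hz is None:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SignalError(f"{path}: timestamps must be strictly increasing")
        rate_hz = 1.0 / float(np.median(dt))
    acc = df[["ax_g", "ay_g", "az_g"]].to_numpy(float)
    gyr = df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(float)
    return ImuSeries(t, acc, gyr, rate_hz)


# --------------------------------------------------------------------------
# labels CSV

def write_labels_csv(labels: Iterable[TrialLabel], path) -> None:
    rows = [
        dict(trial_id=l.trial_id, activity=l.activity, is_fall=int(l.is_fall),
             t_impact_s="" if l.t_impact is None else f"{l.t_impact:.8g}")
        for l in labels
    ]
    pd.DataFrame(rows, columns=list(LABEL_COLUMNS)).to_csv(path, index=False)


def read_labels_csv(path) -> list[TrialLabel]:
    df = pd.read_csv(path)
    for col in LABEL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    labels = []
    for _, row in df.iterrows():
        t_imp = row["t_impact_s"]
        t_imp = None if pd.isna(t_imp) or t_imp == "" else float(t_imp)
        labels.append(
            TrialLabel(str(row["trial_id"]), str(row["activity"]), bool(row["is_fall"]), t_imp)
        )
    return labels


def write_angles_csv(track: OrientationTrack, path) -> None:
    """Export a per-trial angle trajectory as t_s,roll_deg,pitch_deg."""
    data = np.column_stack([track.t, track.roll, track.pitch])
    np.savetxt(path, data, fmt="%.8g", delimiter=",",
               header="t_s,roll_deg,pitch_deg", comments="")


# --------------------------------------------------------------------------
# SisFall

def parse_axis_map(spec) -> dict[str, tuple[int, float]]:
    """Normalise an axis map into {target: (source index, sign)}.

    Accepts a mapping like ``{"x": "+z", "y": "+x", "z": "-y"}`` or the
    equivalent string ``"x=+z,y=+x,z=-y"``.
    """
    if isinstance(spec, str):
        try:
            spec = dict(part.split("=") for part in spec.split(","))
        except ValueError:
            raise ValueError(f"cannot parse axis map string {spec!r}") from None
    src_index = {"x": 0, "y": 1, "z": 2}
    out = {}
    for target in ("x", "y", "z"):
        if target not in spec:
            raise ValueError(f"axis map must define target axis {target!r}")
        s = str(spec[target]).strip()
        sign = 1.0
        if s[0] in "+-":
            sign = -1.0 if s[0] == "-" else 1.0
            s = s[1:]
        if s not in src_index:
            raise ValueError(f"unknown source axis {spec[target]!r} for target {target!r}")
        out[target] = (src_index[s], sign)
    return out


def read_sisfall(path, axis_map, rate_hz: float = 200.0) -> ImuSeries:
    """Read a SisFall-format text recording into an ImuSeries.

    Each line holds 9 comma-separated integers (first accelerometer
    x,y,z; gyroscope x,y,z; second accelerometer x,y,z — ignored), with
    a tolerated trailing ``;``.  Conversions: acceleration raw * 32/8192
    g, angular velocity raw * 4000/65536 deg/s.  ``axis_map`` remaps the
    device axes onto this package's convention and is mandatory
    (placement differs between datasets); see DEFAULT_SISFALL_AXIS_MAP
    for a documented starting guess.
    """
    amap = parse_axis_map(axis_map)
    if axis_map is DEFAULT_SISFALL_AXIS_MAP:
        log.warning(
            "using the default SisFall axis-map guess; results depend on it — "
            "verify against a standing segment of the data"
        )
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";").rstrip(",")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 9:
                raise SisFallFormatError(f"{path}: line {lineno}: expected 9 columns, got {len(parts)}")
            try:
                rows.append([int(p) for p in parts])
            except ValueError as exc:
                raise SisFallFormatError(f"{path}: line {lineno}: {exc}") from None
    raw = np.asarray(rows, dtype=float)
    if raw.shape[0] < 2:
        raise SisFallFormatError(f"{path}: fewer than 2 parsable samples")
    acc_dev = raw[:, 0:3] * SISFALL_ACC_SCALE_G
    gyr_dev = raw[:, 3:6] * SISFALL_GYR_SCALE_DPS
    acc = np.column_stack([amap[a][1] * acc_dev[:, amap[a][0]] for a in ("x", "y", "z")])
    gyr = np.column_stack([amap[a][1] * gyr_dev[:, amap[a][0]] for a in ("x", "y", "z")])
    t = np.arange(raw.shape[0]) / rate_hz
    return ImuSeries(t, acc, gyr, rate_hz)


# --------------------------------------------------------------------------
# pipeline configuration (YAML)

@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the detection pipeline on a raw trial."""

    detector: DetectorConfig = DetectorConfig()
    gains: FilterGains = FilterGains()
    cutoff_hz: float = 5.0
    zero_phase: bool = False
    correction: str = "post"
    accel_gate: bool = False
    i_limit_deg: float = 20.0

    def feature_opts(self) -> dict:
        return dict(
            cutoff_hz=self.cutoff_hz,
            zero_phase=self.zero_phase,
            gains=self.gains,
            correction=self.correction,
            accel_gate=self.accel_gate,
            i_limit_deg=self.i_limit_deg,
        )

    def to_dict(self) -> dict:
        return {
            "detector": dataclasses.asdict(self.detector),
            "gains": dataclasses.asdict(self.gains),
            "filter": {"cutoff_hz": self.cutoff_hz, "zero_phase": self.zero_phase},
            "orientation": {
                "correction": self.correction,
                "accel_gate": self.accel_gate,
                "i_limit_deg": self.i_limit_deg,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        det = DetectorConfig(**d.get("detector", {}))
        gains = FilterGains(**d.get("gains", {}))
        filt = d.get("filter", {})
        ori = d.get("orientation", {})
        return cls(
            detector=det,
            gains=gains,
            cutoff_hz=float(filt.get("cutoff_hz", 5.0)),
            zero_phase=bool(filt.get("zero_phase", False)),
            correction=str(ori.get("correction", "post")),
            accel_gate=bool(ori.get("accel_gate", False)),
            i_limit_deg=float(ori.get("i_limit_deg", 20.0)),
        )


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True, default_flow_style=False)
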