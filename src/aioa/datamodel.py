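"""Sensor-stream containers, CSV I/O and window segmentation.

Two streams are modelled: triaxial acceleration sampled at a nominal 25 Hz
(units of g) and GPS fixes at a nominal one fix per 60 s (decimal degrees,
WGS84).  Both may carry a per-record behaviour label.  Timestamps are
seconds as decimal numbers, zero-based from deployment start; the methods
only need relative cadence, so absolute datetimes are deliberately out of
scope.

Windowing follows the on-device cadences: acceleration is classified on
non-overlapping 1-s windows (25 samples) of acceleration *magnitude*, GPS
on sliding 10-fix (10-min) windows advanced one fix per minute.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParseError, ValidationError

ACC_BEHAVIOURS = ("stationary", "flying", "foraging")
GPS_BEHAVIOURS = ("stationary", "transit", "ARS")

#: nominal acceleration sampling interval (s) and allowed relative jitter
ACC_DT = 0.04
ACC_DT_RTOL = 0.01
#: nominal GPS fix interval (s)
GPS_DT = 60.0


def _check_labels(labels, n: int, allowed: tuple[str, ...]) -> np.ndarray | None:
    if labels is None:
        return None
    labels = np.asarray(labels, dtype=object)
    if len(labels) != n:
        raise ValidationError(
            f"labels length {len(labels)} does not match series length {n}"
        )
    bad = set(labels) - set(allowed)
    if bad:
        raise ValidationError(f"unknown behaviour labels: {sorted(map(str, bad))}")
    return labels


@dataclass
class AccSeries:
    """Triaxial acceleration stream (g) at a nominal 25 Hz."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValidationError("acceleration channels must have equal length")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"timestamps must be strictly increasing (violated at index {i + 1})"
                )
            if np.any(np.abs(dt - ACC_DT) > ACC_DT_RTOL * ACC_DT):
                i = int(np.argmax(np.abs(dt - ACC_DT) > ACC_DT_RTOL * ACC_DT))
                raise ValidationError(
                    f"sampling interval {dt[i]:.6g} s at index {i + 1} deviates more "
                    f"than {ACC_DT_RTOL:.0%} from the nominal {ACC_DT} s"
                )
        self.labels = _check_labels(self.labels, n, ACC_BEHAVIOURS)

    def __len__(self) -> int:
        return len(self.t)

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of each (ax, ay, az) sample; orientation-free."""
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"timestamp": self.t, "ax": self.ax, "ay": self.ay, "az": self.az})
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        write_acc_csv(self, path)


@dataclass
class GpsSeries:
    """GPS fix stream (decimal degrees) at a nominal one fix per minute."""

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        n = len(self.t)
        if not (len(self.lat) == len(self.lon) == n):
            raise ValidationError("lat/lon must match timestamp length")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValidationError("latitude/longitude out of range")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        self.labels = _check_labels(self.labels, n, GPS_BEHAVIOURS)

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"timestamp": self.t, "lat": self.lat, "lon": self.lon})
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        write_gps_csv(self, path)


@dataclass
class MagWindow:
    """One nominal second (25 samples) of acceleration magnitude."""

    values: np.ndarray
    label: str | None = None
    index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("acceleration magnitudes must be non-negative")


@dataclass
class GpsWindow:
    """Ten consecutive fixes: the 10-min GPS classification window."""

    lat: np.ndarray
    lon: np.ndarray
    label: str | None = None
    index: int = 0

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if len(self.lat) != len(self.lon):
            raise ValidationError("lat/lon length mismatch in window")


@dataclass
class RunConfig:
    """Resolved run configuration; every artifact records its seed."""

    window_length: int = 25
    window_step: int = 25
    noise_level: float = 0.2
    arm_count: int = 5
    disarm_count: int = 10
    consecutive_ars: int = 2
    video_duration_s: float = 60.0
    camera_startup_delay_s: float = 3.0
    battery_sensing_hours: float = 20.0
    battery_video_hours: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("video_duration_s", "camera_startup_delay_s",
                     "battery_sensing_hours", "battery_video_hours"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# CSV I/O


def _read_sensor_csv(path, required: Sequence[str]):
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"could not read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.values))
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"'{col}' at data row {row}", row=row,
            )
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().values))
            raise ParseError(f"{path}: missing value in column '{col}' at data row {row}",
                             row=row)
        df[col] = coerced
    return df


def read_acc_csv(path) -> AccSeries:
    """Read an acceleration CSV: ``timestamp,ax,ay,az[,label]``."""
    df = _read_sensor_csv(path, ("timestamp", "ax", "ay", "az"))
    labels = df["label"].to_numpy(dtype=object) if "label" in df.columns else None
    return AccSeries(df["timestamp"].to_numpy(), df["ax"].to_numpy(),
                     df["ay"].to_numpy(), df["az"].to_numpy(), labels)


def write_acc_csv(series: AccSeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def read_gps_csv(path) -> GpsSeries:
    """Read a GPS CSV: ``timestamp,lat,lon[,label]``."""
    df = _read_sensor_csv(path, ("timestamp", "lat", "lon"))
    labels = df["label"].to_numpy(dtype=object) if "label" in df.columns else None
    return GpsSeries(df["timestamp"].to_numpy(), df["lat"].to_numpy(),
                     df["lon"].to_numpy(), labels)


def write_gps_csv(series: GpsSeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False, float_format="%.7f")


# ---------------------------------------------------------------------------
# Windowing


def majority_label(labels: Sequence[str], rarity_order: Sequence[str] | None = None) -> str:
    """Majority vote over member labels, ties broken toward the rarer class.

    ``rarity_order`` lists classes from rarest to most common (used for
    tie-breaking); by default ties go to the lexicographically earlier of
    the globally rarer candidates, computed from the labels themselves.
    """
    labels = list(labels)
    values, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    top = counts.max()
    tied = [str(v) for v, c in zip(values, counts) if c == top]
    if len(tied) == 1:
        return tied[0]
    if rarity_order is not None:
        rank = {c: i for i, c in enumerate(rarity_order)}
        return min(tied, key=lambda c: (rank.get(c, len(rank)), c))
    return min(tied)


def _series_rarity_order(labels: np.ndarray) -> list[str]:
    values, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    order = sorted(zip(counts, map(str, values)))
    return [v for _, v in order]


def segment_windows(series, length: int | None = None, step: int | None = None):
    """Cut a sensor series into classification windows.

    Acceleration series yield :class:`MagWindow` objects built from the
    magnitude signal (default 25 samples, step 25: non-overlapping 1-s
    windows).  GPS series yield :class:`GpsWindow` objects (default 10
    fixes, step 1: sliding once-per-minute windows).  A series shorter than
    one window yields an empty list.  Window labels are the majority label
    of the members, ties broken toward the class that is rarer in the whole
    series (the target behaviour is always the rarest).
    """
    if isinstance(series, AccSeries):
        length = 25 if length is None else length
        step = length if step is None else step
        values = series.magnitude()
        make = lambda sl, lab, i: MagWindow(values[sl], lab, i)  # noqa: E731
        labels = series.labels
    elif isinstance(series, GpsSeries):
        length = 10 if length is None else length
        step = 1 if step is None else step
        make = lambda sl, lab, i: GpsWindow(series.lat[sl], series.lon[sl], lab, i)  # noqa: E731
        labels = series.labels
    else:
        raise TypeError(f"cannot segment {type(series).__name__}")
    if length < 1 or step < 1:
        raise ValidationError("window length and step must be >= 1")
    n = len(series)
    if n < length:
        return []
    rarity = _series_rarity_order(labels) if labels is not None else None
    out = []
    for i, start in enumerate(range(0, n - length + 1, step)):
        sl = slice(start, start + length)
        lab = majority_label(labels[sl], rarity) if labels is not None else None
        out.append(make(sl, lab, i))
    return out


def window_labels(windows) -> np.ndarray:
    """Convenience: array of labels from a window sequence."""
    return np.asarray([w.label for w in windows], dtype=object)
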