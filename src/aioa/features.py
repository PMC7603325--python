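"""Window feature extraction for acceleration magnitude and GPS tracks.

Acceleration features are simple time-domain statistics of the 1-s
magnitude window — the kind that fit in a few hundred bytes of MCU program
memory.  Moments are population moments (no bias correction), kurtosis is
non-excess (``m4/m2**2``), and both kurtosis and skewness are defined as 0
on a constant window.  The scalar extractors below are written as plain
sequential loops so that the generated C translations in :mod:`aioa.codegen`
are line-for-line equivalent; :func:`acc_feature_table` is the vectorised
batch path used by pipelines and is checked against the scalar path in the
test-suite.

GPS features describe a 10-fix (10-min) window: path geometry from
haversine distances (mean Earth radius 6 371 000 m) and axis statistics
after a coarse rotation search.  The rotation search mean-centres the
(lon, lat) pairs, treats them as planar coordinates, and evaluates the
candidate angles 0°, 22.5°, 45°, 67.5° and 90°, keeping the one that
maximises the variance of the rotated longitudes.  The "primary" axis is
the rotated longitude axis (maximised variance), the "secondary" axis the
perpendicular one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .datamodel import GpsWindow, MagWindow
from .errors import SchemaError, ValidationError

EARTH_RADIUS_M = 6_371_000.0
ROTATION_ANGLES_DEG = (0.0, 22.5, 45.0, 67.5, 90.0)
GPS_FIX_INTERVAL_S = 60.0


def magnitude(ax, ay, az):
    """Euclidean norm of a triaxial sample; invariant under 3-D rotation."""
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    return np.sqrt(ax * ax + ay * ay + az * az)


# ---------------------------------------------------------------------------
# Scalar acceleration extractors (mirrored 1:1 by the C templates)


def f_mean(w: Sequence[float]) -> float:
    s = 0.0
    for v in w:
        s += v
    return s / len(w)


def f_variance(w: Sequence[float]) -> float:
    m = f_mean(w)
    s = 0.0
    for v in w:
        s += (v - m) * (v - m)
    return s / len(w)


def f_std(w: Sequence[float]) -> float:
    return math.sqrt(f_variance(w))


def f_min(w: Sequence[float]) -> float:
    out = w[0]
    for v in w:
        if v < out:
            out = v
    return out


def f_max(w: Sequence[float]) -> float:
    out = w[0]
    for v in w:
        if v > out:
            out = v
    return out


def f_range(w: Sequence[float]) -> float:
    return f_max(w) - f_min(w)


def f_rms(w: Sequence[float]) -> float:
    s = 0.0
    for v in w:
        s += v * v
    return math.sqrt(s / len(w))


def f_crest(w: Sequence[float]) -> float:
    """Peak over RMS; 0 on an all-zero window by convention."""
    r = f_rms(w)
    if r == 0.0:
        return 0.0
    return f_max(w) / r


def f_kurtosis(w: Sequence[float]) -> float:
    """Population, non-excess kurtosis m4/m2^2; 0 on a constant window."""
    m = f_mean(w)
    m2 = 0.0
    m4 = 0.0
    for v in w:
        d = v - m
        m2 += d * d
        m4 += d * d * d * d
    m2 /= len(w)
    m4 /= len(w)
    if m2 == 0.0:
        return 0.0
    return m4 / (m2 * m2)


def f_skewness(w: Sequence[float]) -> float:
    """Population skewness m3/m2^1.5; 0 on a constant window."""
    m = f_mean(w)
    m2 = 0.0
    m3 = 0.0
    for v in w:
        d = v - m
        m2 += d * d
        m3 += d * d * d
    m2 /= len(w)
    m3 /= len(w)
    if m2 == 0.0:
        return 0.0
    return m3 / (m2 * math.sqrt(m2))


def f_meancross(w: Sequence[float]) -> float:
    """Count of consecutive pairs strictly straddling the window mean."""
    m = f_mean(w)
    c = 0
    for i in range(len(w) - 1):
        if (w[i] - m) * (w[i + 1] - m) < 0.0:
            c += 1
    return float(c)


def f_meanabsdiff(w: Sequence[float]) -> float:
    """Mean absolute first difference (signal roughness)."""
    s = 0.0
    for i in range(len(w) - 1):
        s += abs(w[i + 1] - w[i])
    return s / (len(w) - 1)


ACC_EXTRACTORS: dict[str, Callable[[Sequence[float]], float]] = {
    "mean": f_mean,
    "variance": f_variance,
    "std": f_std,
    "min": f_min,
    "max": f_max,
    "range": f_range,
    "rms": f_rms,
    "crest": f_crest,
    "kurtosis": f_kurtosis,
    "skewness": f_skewness,
    "meancross": f_meancross,
    "meanabsdiff": f_meanabsdiff,
}


# ---------------------------------------------------------------------------
# Catalogue


@dataclass
class CatalogueEntry:
    extractor: str
    size_bytes: int
    params: dict = field(default_factory=dict)
    from_source: bool = False  # True only for byte costs taken from published figures


class FeatureCatalogue:
    """Named feature extractors with their program-memory byte costs.

    The byte cost is what drives cost-weighted tree induction: features are
    sampled as split candidates with probability proportional to
    ``1/size_bytes``.
    """

    def __init__(self, entries: Mapping[str, CatalogueEntry]):
        self.entries = dict(entries)
        for name, e in self.entries.items():
            if e.size_bytes <= 0:
                raise ValidationError(f"feature {name!r}: size_bytes must be > 0")

    def __contains__(self, name) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def size_bytes(self, name: str) -> int:
        return self.entries[name].size_bytes

    @property
    def sizes(self) -> np.ndarray:
        return np.array([e.size_bytes for e in self.entries.values()], dtype=float)

    def to_yaml(self, path) -> None:
        data = {
            name: {"extractor": e.extractor, "size_bytes": e.size_bytes,
                   "params": e.params, "from_source": e.from_source}
            for name, e in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureCatalogue":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: catalogue file must map names to entries")
        entries = {}
        for name, raw in data.items():
            try:
                entries[name] = CatalogueEntry(
                    extractor=raw["extractor"],
                    size_bytes=int(raw["size_bytes"]),
                    params=raw.get("params", {}) or {},
                    from_source=bool(raw.get("from_source", False)),
                )
            except (KeyError, TypeError) as exc:
                raise SchemaError(f"{path}: bad catalogue entry {name!r}: {exc}") from exc
        return cls(entries)


# Default byte costs. Only kurtosis (680 B) is anchored to a published MCU
# implementation; the rest are order-of-magnitude placeholders reflecting
# relative code complexity and are flagged from_source=False.
_DEFAULT_ACC_SIZES = {
    "mean": 120,
    "variance": 210,
    "std": 270,
    "min": 90,
    "max": 90,
    "range": 140,
    "rms": 230,
    "crest": 290,
    "kurtosis": 680,
    "skewness": 620,
    "meancross": 160,
    "meanabsdiff": 150,
}


def default_acc_catalogue() -> FeatureCatalogue:
    entries = {
        name: CatalogueEntry(extractor=name, size_bytes=size,
                             from_source=(name == "kurtosis"))
        for name, size in _DEFAULT_ACC_SIZES.items()
    }
    return FeatureCatalogue(entries)


GPS_FEATURE_NAMES = (
    "total_distance", "net_displacement", "avg_speed", "max_leg_speed",
    "straightness", "rotation", "primary_variance", "secondary_variance",
    "primary_meancross", "secondary_meancross",
)

_DEFAULT_GPS_SIZES = {
    "total_distance": 420,
    "net_displacement": 400,
    "avg_speed": 450,
    "max_leg_speed": 470,
    "straightness": 520,
    "rotation": 380,
    "primary_variance": 360,
    "secondary_variance": 360,
    "primary_meancross": 330,
    "secondary_meancross": 330,
}


def default_gps_catalogue() -> FeatureCatalogue:
    entries = {
        name: CatalogueEntry(extractor=name, size_bytes=size)
        for name, size in _DEFAULT_GPS_SIZES.items()
    }
    return FeatureCatalogue(entries)


# ---------------------------------------------------------------------------
# Acceleration feature extraction


def extract_acc_features(window: MagWindow, catalogue: FeatureCatalogue) -> dict[str, float]:
    """Feature vector (ordered as the catalogue) for one magnitude window."""
    w = [float(v) for v in window.values]
    out = {}
    for name, entry in catalogue.entries.items():
        try:
            fn = ACC_EXTRACTORS[entry.extractor]
        except KeyError:
            raise SchemaError(f"unknown acceleration extractor {entry.extractor!r}")
        out[name] = fn(w)
    return out


def acc_feature_table(windows: Sequence[MagWindow],
                      catalogue: FeatureCatalogue) -> np.ndarray:
    """Vectorised (n_windows, n_features) table in catalogue order."""
    if len(windows) == 0:
        return np.empty((0, len(catalogue)))
    return feature_table_matrix(np.stack([w.values for w in windows]), catalogue)


def feature_table_matrix(M: np.ndarray, catalogue: FeatureCatalogue) -> np.ndarray:
    """Vectorised feature table for an (n_windows, window_len) value matrix."""
    M = np.asarray(M, dtype=float)
    mean = M.mean(axis=1)
    dev = M - mean[:, None]
    m2 = (dev**2).mean(axis=1)
    m3 = (dev**3).mean(axis=1)
    m4 = (dev**4).mean(axis=1)
    mn = M.min(axis=1)
    mx = M.max(axis=1)
    rms = np.sqrt((M**2).mean(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        crest = np.where(rms == 0, 0.0, mx / np.where(rms == 0, 1.0, rms))
        kurt = np.where(m2 == 0, 0.0, m4 / np.where(m2 == 0, 1.0, m2) ** 2)
        skew = np.where(m2 == 0, 0.0,
                        m3 / np.where(m2 == 0, 1.0, m2) ** 1.5)
    cross = ((dev[:, :-1] * dev[:, 1:]) < 0).sum(axis=1).astype(float)
    mad = np.abs(np.diff(M, axis=1)).mean(axis=1)
    columns = {
        "mean": mean, "variance": m2, "std": np.sqrt(m2), "min": mn, "max": mx,
        "range": mx - mn, "rms": rms, "crest": crest, "kurtosis": kurt,
        "skewness": skew, "meancross": cross, "meanabsdiff": mad,
    }
    cols = []
    for name, entry in catalogue.entries.items():
        if entry.extractor not in columns:
            raise SchemaError(f"unknown acceleration extractor {entry.extractor!r}")
        cols.append(columns[entry.extractor])
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# GPS feature extraction


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres (mean Earth radius 6 371 000 m)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _rotated_xy(window: GpsWindow, angle_deg: float):
    """Mean-centred planar (lon, lat) rotated by ``angle_deg``."""
    x = window.lon - window.lon.mean()
    y = window.lat - window.lat.mean()
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    # clockwise point rotation: a track heading at bearing angle_deg from
    # east maps onto the longitude axis, maximising longitude variance there
    return x * c + y * s, -x * s + y * c


def best_rotation(window: GpsWindow,
                  angles=ROTATION_ANGLES_DEG) -> float:
    """Candidate angle maximising post-rotation longitude variance.

    Identical fixes (zero variance everywhere) return 0.0; ties go to the
    smallest candidate angle.
    """
    best_angle, best_var = angles[0], -1.0
    for a in angles:
        xr, _ = _rotated_xy(window, a)
        v = float(np.var(xr))
        if v > best_var:
            best_angle, best_var = a, v
    return float(best_angle)


def _meancross_arr(v: np.ndarray) -> float:
    d = v - v.mean()
    return float(((d[:-1] * d[1:]) < 0).sum())


def extract_gps_features(window: GpsWindow,
                         catalogue: FeatureCatalogue | None = None) -> dict[str, float]:
    """Feature vector for one 10-fix GPS window.

    Speeds use the nominal fix interval (60 s per leg; the window spans
    ``n_fixes * 60`` s).  Straightness (net displacement over path length)
    is defined as 1 for a degenerate zero-length path.
    """
    catalogue = catalogue if catalogue is not None else default_gps_catalogue()
    lat, lon = window.lat, window.lon
    n = len(lat)
    legs = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]) if n > 1 else np.array([])
    total = float(legs.sum())
    net = float(haversine_m(lat[0], lon[0], lat[-1], lon[-1])) if n > 1 else 0.0
    duration = n * GPS_FIX_INTERVAL_S
    angle = best_rotation(window)
    xr, yr = _rotated_xy(window, angle)
    values = {
        "total_distance": total,
        "net_displacement": net,
        "avg_speed": total / duration,
        "max_leg_speed": float(legs.max() / GPS_FIX_INTERVAL_S) if len(legs) else 0.0,
        "straightness": 1.0 if total == 0.0 else net / total,
        "rotation": angle,
        "primary_variance": float(np.var(xr)),
        "secondary_variance": float(np.var(yr)),
        "primary_meancross": _meancross_arr(xr),
        "secondary_meancross": _meancross_arr(yr),
    }
    out = {}
    for name, entry in catalogue.entries.items():
        if entry.extractor not in values:
            raise SchemaError(f"unknown GPS extractor {entry.extractor!r}")
        out[name] = values[entry.extractor]
    return out


def gps_feature_table(windows: Sequence[GpsWindow],
                      catalogue: FeatureCatalogue | None = None) -> np.ndarray:
    catalogue = catalogue if catalogue is not None else default_gps_catalogue()
    if len(windows) == 0:
        return np.empty((0, len(catalogue)))
    rows = [list(extract_gps_features(w, catalogue).values()) for w in windows]
    return np.asarray(rows, dtype=float)


def feature_table_dataframe(windows, catalogue):
    """Feature table as a DataFrame with a ``label`` column when available."""
    import pandas as pd

    if len(windows) and isinstance(windows[0], MagWindow):
        X = acc_feature_table(windows, catalogue)
    else:
        X = gps_feature_table(windows, catalogue)
    df = pd.DataFrame(X, columns=catalogue.names)
    labels = [w.label for w in windows]
    if any(l is not None for l in labels):
        df["label"] = labels
    return df
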