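"""Orientation and noise robustness: augmentation and experiment harness.

Loggers end up taped to different body positions and orientations, so a
classifier trained on one year's attachment must survive arbitrary device
rotation and loose-attachment noise.  Two defences are implemented:

* extracting features from the acceleration *magnitude*, which is exactly
  rotation-invariant; and
* augmenting the training windows with copies whose magnitudes are scaled
  by a random multiplicative factor (field setting: level 0.2, i.e. one
  factor per window drawn from Uniform(0.8, 1.2)).

:func:`rotation_experiment` reproduces the comparison between raw
triaxial features, magnitude features, and rotation-augmented raw features
under test-time device rotation.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel import AccSeries, MagWindow, segment_windows
from .errors import ValidationError
from .features import (
    FeatureCatalogue,
    acc_feature_table,
    default_acc_catalogue,
    feature_table_matrix,
)
from .trees import InductionParams, grow_tree, uniform_weights


def rotate_triaxial(series: AccSeries, rotation: np.ndarray) -> AccSeries:
    """Apply a proper 3-D rotation to every (ax, ay, az) sample."""
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
            or not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
        raise ValidationError("rotation must be orthonormal with determinant +1")
    xyz = np.vstack([series.ax, series.ay, series.az])
    rx, ry, rz = R @ xyz
    return AccSeries(series.t.copy(), rx, ry, rz,
                     None if series.labels is None else series.labels.copy())


def rotation_about_axis(axis: str, angle_deg: float) -> np.ndarray:
    """Rotation matrix about one device axis."""
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValidationError(f"unknown axis {axis!r}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def augment_noise(windows: Sequence[MagWindow], level: float,
                  rng: np.random.Generator,
                  distribution: str = "uniform") -> list[MagWindow]:
    """Originals plus noisy copies: one multiplicative factor per window.

    At noise level ``level`` the factor is drawn from
    Uniform(1 - level, 1 + level) (or Normal(1, level) with
    ``distribution="gaussian"``).  Labels are preserved and the output has
    exactly twice as many windows as the input.
    """
    if level < 0:
        raise ValidationError("noise level must be >= 0")
    if level >= 1:
        warnings.warn("noise level >= 1: scale factors may reach zero or below")
    out = list(windows)
    n = len(windows)
    if distribution == "uniform":
        factors = rng.uniform(1.0 - level, 1.0 + level, size=n)
    elif distribution == "gaussian":
        factors = rng.normal(1.0, level, size=n)
    else:
        raise ValidationError(f"unknown factor distribution {distribution!r}")
    for w, f in zip(windows, factors):
        out.append(MagWindow(np.abs(w.values * f), w.label, w.index))
    return out


# ---------------------------------------------------------------------------
# Rotation experiment


def triaxial_feature_table(series: AccSeries, catalogue: FeatureCatalogue,
                           length: int = 25):
    """Per-axis feature table (orientation-sensitive raw representation).

    Each catalogue extractor is applied to ax, ay and az separately,
    giving ``3 * len(catalogue)`` columns named ``<feature>_<axis>``.
    """
    windows_lab = segment_windows(series, length, length)
    labels = np.asarray([w.label for w in windows_lab], dtype=object)
    n_win = len(windows_lab)
    tables = []
    names = []
    for axis_name, channel in (("ax", series.ax), ("ay", series.ay), ("az", series.az)):
        M = channel[: n_win * length].reshape(n_win, length)
        tables.append(feature_table_matrix(M, catalogue))
        names.extend(f"{f}_{axis_name}" for f in catalogue.names)
    return np.hstack(tables), names, labels


def magnitude_feature_table(series: AccSeries, catalogue: FeatureCatalogue,
                            length: int = 25):
    windows = segment_windows(series, length, length)
    labels = np.asarray([w.label for w in windows], dtype=object)
    return acc_feature_table(windows, catalogue), list(catalogue.names), labels


def _expanded_catalogue(catalogue: FeatureCatalogue, names: list[str]) -> FeatureCatalogue:
    from .features import CatalogueEntry

    entries = {}
    for name in names:
        base = name.rsplit("_", 1)[0] if name.rsplit("_", 1)[-1] in ("ax", "ay", "az") \
            else name
        e = catalogue.entries[base]
        entries[name] = CatalogueEntry(e.extractor, e.size_bytes, dict(e.params))
    return FeatureCatalogue(entries)


def rotation_experiment(train: AccSeries, test: AccSeries,
                        angles_deg: Sequence[float] = (0, 45, 90, 135, 180),
                        axis: str = "x",
                        catalogue: FeatureCatalogue | None = None,
                        params: InductionParams | None = None,
                        n_augment_rotations: int = 8,
                        seed: int = 0) -> pd.DataFrame:
    """Accuracy vs test-time rotation for three feature pipelines.

    Rows: ``raw`` (per-axis features), ``magnitude`` (rotation-invariant
    magnitude features), ``raw_augmented`` (per-axis features trained with
    randomly rotated copies of the training data).  Columns: test accuracy
    at each device rotation angle about ``axis``.
    """
    catalogue = catalogue if catalogue is not None else default_acc_catalogue()
    params = params if params is not None else InductionParams()
    rng = np.random.default_rng(seed)

    def fit(X, y, names, cat):
        w = uniform_weights(cat)
        return grow_tree(X, y, names, cat, params, np.random.default_rng(
            int(rng.integers(2**31))), weights={f: w[f] for f in names})

    # raw pipeline
    Xr, raw_names, yr = triaxial_feature_table(train, catalogue)
    raw_cat = _expanded_catalogue(catalogue, raw_names)
    raw_tree = fit(Xr, yr, raw_names, raw_cat)
    # magnitude pipeline
    Xm, mag_names, ym = magnitude_feature_table(train, catalogue)
    mag_tree = fit(Xm, ym, mag_names, catalogue)
    # rotation-augmented raw pipeline
    Xa, ya = [Xr], [yr]
    for _ in range(n_augment_rotations):
        rot = rotate_triaxial(train, random_rotation(rng))
        Xi, _, yi = triaxial_feature_table(rot, catalogue)
        Xa.append(Xi)
        ya.append(yi)
    aug_tree = fit(np.vstack(Xa), np.concatenate(ya), raw_names, raw_cat)

    rows = {"raw": [], "magnitude": [], "raw_augmented": []}
    for a in angles_deg:
        rotated = rotate_triaxial(test, rotation_about_axis(axis, a))
        Xt, _, yt = triaxial_feature_table(rotated, catalogue)
        Xtm, _, ytm = magnitude_feature_table(rotated, catalogue)
        rows["raw"].append(float((raw_tree.predict_table(Xt, raw_names) == yt).mean()))
        rows["magnitude"].append(
            float((mag_tree.predict_table(Xtm, mag_names) == ytm).mean()))
        rows["raw_augmented"].append(
            float((aug_tree.predict_table(Xt, raw_names) == yt).mean()))
    return pd.DataFrame(rows, index=[float(a) for a in angles_deg]).T
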