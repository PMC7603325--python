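"""Shared test helper: a dataset where orientation IS the class signal."""

import numpy as np

from aioa.datamodel import AccSeries


def orientation_informative_series(n_seconds: int = 120, seed: int = 0) -> AccSeries:
    """Two classes differing only in the sign of the z axis.

    The magnitude signal is identically distributed for both classes, so
    magnitude features classify at chance while raw per-axis features
    separate perfectly — until the device is rotated.
    """
    rng = np.random.default_rng(seed)
    labs, az = [], []
    for i in range(n_seconds):
        lab = "stationary" if i % 2 == 0 else "flying"
        sign = 1.0 if lab == "stationary" else -1.0
        labs += [lab] * 25
        az.append(sign + rng.normal(0, 0.05, 25))
    n = n_seconds * 25
    t = np.arange(n) * 0.04
    return AccSeries(t, rng.normal(0, 0.05, n), rng.normal(0, 0.05, n),
                     np.concatenate(az), np.array(labs, dtype=object))
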