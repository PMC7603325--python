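"""Labelled synthetic sensor streams with the structure the method assumes.

No public accession exists for the field recordings, so every pipeline
stage is exercised on generated data that emulates their statistical
structure rather than their waveforms:

* **Acceleration** (gull-like): quiescent stationary baseline around 1 g,
  high-amplitude ~4 Hz sinusoidal flapping during flight, and brief
  high-variance dip/surge events — the labelled target signature — during
  foraging.  Foraging occurs embedded in flight bouts, matching how a
  foraging dip interrupts flapping, and its prevalence defaults to the
  field estimate (~1.6%, with ~10% flying and ~88.4% stationary).
* **GPS** (shearwater-like): a correlated random walk whose turning-angle
  concentration separates directed transit from tortuous area-restricted
  search (ARS), with a near-stationary drift regime; default mix ~23.2%
  ARS / 34.4% transit / 42.4% stationary.

Generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import AccSeries, GpsSeries, RunConfig
from .errors import ValidationError
from .features import default_acc_catalogue, default_gps_catalogue

SUITE_VERSION = 1
ACC_HZ = 25
METRES_PER_DEG_LAT = 111_320.0


@dataclass
class BehaviourSchedule:
    """Ordered (behaviour, duration_s) segments for an acceleration trace."""

    segments: list[tuple[str, float]]

    def __post_init__(self):
        if any(d <= 0 for _, d in self.segments):
            raise ValidationError("segment durations must be > 0")

    @property
    def total_s(self) -> float:
        return sum(d for _, d in self.segments)

    def prevalence(self) -> dict[str, float]:
        tot = self.total_s
        out: dict[str, float] = {}
        for b, d in self.segments:
            out[b] = out.get(b, 0.0) + d
        return {b: v / tot for b, v in out.items()}


@dataclass
class AccSignalParams:
    """Waveform parameters for the three acceleration regimes (units g)."""

    stationary_noise: float = 0.02
    flap_hz: float = 4.0
    flap_amplitude: float = 1.0
    flying_noise: float = 0.08
    dip_noise: float = 0.30
    dip_spike_prob: float = 0.30   # per-sample chance of a dip/surge spike
    dip_spike_min: float = 1.5
    dip_spike_max: float = 3.0


DEFAULT_ACC_PREVALENCE = {"stationary": 0.884, "flying": 0.0996, "foraging": 0.016}


def make_acc_schedule(total_s: float,
                      prevalence: dict[str, float] | None = None,
                      rng: np.random.Generator | int = 0) -> BehaviourSchedule:
    """Bout-structured schedule tracking the target class mix.

    Cycles of stationary rest followed by a flight bout with embedded
    foraging dips.  The stationary duration of each cycle is steered so the
    realized class shares stay within about one percentage point of the
    targets for long traces.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    prev = dict(DEFAULT_ACC_PREVALENCE if prevalence is None else prevalence)
    tot = sum(prev.values())
    prev = {k: v / tot for k, v in prev.items()}
    st_share = prev["stationary"]
    if prev["flying"] <= 0.0:  # degenerate: resting-only schedule
        return BehaviourSchedule([("stationary", float(total_s))])
    fo_per_fly = prev["foraging"] / prev["flying"]
    segments: list[tuple[str, float]] = []
    real = {"stationary": 0.0, "flying": 0.0, "foraging": 0.0}
    t = 0.0
    while t < total_s:
        fly_total = rng.gamma(4.0, 25.0 / 4.0) + 8.0
        fo_total = fo_per_fly * fly_total * rng.uniform(0.7, 1.3)
        n_dips = max(1, int(round(fo_total / 3.5)))
        dips = rng.uniform(2.0, 5.0, size=n_dips)
        dips *= fo_total / dips.sum()
        # flight split so every dip is preceded by >= 6 s of flying
        fly_parts = rng.uniform(0.5, 1.5, size=n_dips + 1)
        fly_parts = 6.0 + fly_parts / fly_parts.sum() * max(fly_total - 6.0 * (n_dips + 1), 0.0)
        active = fly_total + fo_total
        # stationary time that restores the target stationary share exactly
        need = st_share * (t + active) - real["stationary"]
        st = max(20.0, need / (1.0 - st_share)) * rng.uniform(0.9, 1.1)
        segments.append(("stationary", st))
        real["stationary"] += st
        for i in range(n_dips):
            segments.append(("flying", fly_parts[i]))
            segments.append(("foraging", float(dips[i])))
            real["flying"] += fly_parts[i]
            real["foraging"] += float(dips[i])
        segments.append(("flying", fly_parts[-1]))
        real["flying"] += fly_parts[-1]
        t += st + active
    return BehaviourSchedule(segments)


def make_acc_trace(schedule: BehaviourSchedule,
                   params: AccSignalParams | None = None,
                   seed: int | np.random.Generator = 0) -> AccSeries:
    """Render a schedule as a labelled 25 Hz triaxial trace (units g).

    The gravity vector sits on the z axis; flapping is a sinusoid on z;
    foraging adds heavy-tailed spikes and extra noise on top of the
    flapping background.
    """
    params = params if params is not None else AccSignalParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ax_parts, ay_parts, az_parts, lab_parts = [], [], [], []
    for behaviour, dur in schedule.segments:
        n = max(1, int(round(dur * ACC_HZ)))
        tloc = np.arange(n) / ACC_HZ
        if behaviour == "stationary":
            ax = rng.normal(0.0, params.stationary_noise, n)
            ay = rng.normal(0.0, params.stationary_noise, n)
            az = 1.0 + rng.normal(0.0, params.stationary_noise, n)
        elif behaviour in ("flying", "foraging"):
            phase = rng.uniform(0, 2 * math.pi)
            flap = params.flap_amplitude * np.sin(
                2 * math.pi * params.flap_hz * tloc + phase)
            noise = params.flying_noise if behaviour == "flying" else params.dip_noise
            ax = rng.normal(0.0, noise, n)
            ay = rng.normal(0.0, noise, n)
            az = 1.0 + flap + rng.normal(0.0, noise, n)
            if behaviour == "foraging":
                spikes = rng.random(n) < params.dip_spike_prob
                az = az + spikes * rng.uniform(
                    params.dip_spike_min, params.dip_spike_max, n) * \
                    rng.choice([-1.0, 1.0], n)
        else:
            raise ValidationError(f"unknown behaviour {behaviour!r}")
        ax_parts.append(ax)
        ay_parts.append(ay)
        az_parts.append(az)
        lab_parts.append(np.full(n, behaviour, dtype=object))
    ax = np.concatenate(ax_parts)
    t = np.arange(len(ax)) / ACC_HZ
    return AccSeries(t, ax, np.concatenate(ay_parts), np.concatenate(az_parts),
                     np.concatenate(lab_parts))


def make_gull_series(total_s: float, seed: int,
                     prevalence: dict[str, float] | None = None,
                     params: AccSignalParams | None = None) -> AccSeries:
    """Schedule plus trace in one call (single seed, two derived streams)."""
    root = np.random.default_rng(seed)
    sched_rng, trace_rng = root.spawn(2)
    schedule = make_acc_schedule(total_s, prevalence, sched_rng)
    return make_acc_trace(schedule, params, trace_rng)


# ---------------------------------------------------------------------------
# GPS movement


@dataclass
class MovementRegimeParams:
    """Correlated-random-walk parameters per movement regime.

    ``turn_sd`` is the standard deviation (radians) of the per-minute
    heading increment: small for directed transit, large for tortuous ARS.
    """

    speeds_mps: dict = field(default_factory=lambda: {
        "transit": 10.0, "ARS": 4.0, "stationary": 0.05})
    speed_sd: dict = field(default_factory=lambda: {
        "transit": 1.0, "ARS": 1.0, "stationary": 0.03})
    turn_sd: dict = field(default_factory=lambda: {
        "transit": 0.05, "ARS": 1.8, "stationary": math.pi})
    bout_mean_s: dict = field(default_factory=lambda: {
        "transit": 900.0, "ARS": 720.0, "stationary": 900.0})
    prevalence: dict = field(default_factory=lambda: {
        "ARS": 0.232, "transit": 0.344, "stationary": 0.424})


def make_gps_track(params: MovementRegimeParams | None = None,
                   total_s: float = 6 * 3600.0,
                   seed: int | np.random.Generator = 0,
                   start_lat: float = 38.5, start_lon: float = 139.2) -> GpsSeries:
    """Labelled one-fix-per-minute track switching between regimes."""
    params = params if params is not None else MovementRegimeParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_fix = int(total_s // 60)
    prev = params.prevalence
    real = {k: 0.0 for k in prev}
    lat = np.empty(n_fix)
    lon = np.empty(n_fix)
    labels = np.empty(n_fix, dtype=object)
    lat[0], lon[0] = start_lat, start_lon
    heading = rng.uniform(0, 2 * math.pi)
    i = 0
    while i < n_fix:
        total_real = sum(real.values()) or 1.0
        deficits = {k: prev[k] - real[k] / total_real for k in prev}
        regime = max(deficits, key=lambda k: (deficits[k], k))
        bout_fixes = max(3, int(rng.gamma(4.0, params.bout_mean_s[regime] / 4.0) // 60))
        # cap the bout so the regime's share cannot overshoot its target
        p = prev[regime]
        if p < 1.0:
            cap = (p * total_real - real[regime]) / (60.0 * (1.0 - p))
            bout_fixes = min(bout_fixes, max(3, int(math.ceil(cap)) + 3))
        for _ in range(bout_fixes):
            if i >= n_fix:
                break
            labels[i] = regime
            if i + 1 < n_fix:
                heading = heading + rng.normal(0.0, params.turn_sd[regime])
                speed = max(0.0, rng.normal(params.speeds_mps[regime],
                                            params.speed_sd[regime]))
                step = speed * 60.0
                dy = step * math.cos(heading)
                dx = step * math.sin(heading)
                lat[i + 1] = lat[i] + dy / METRES_PER_DEG_LAT
                lon[i + 1] = lon[i] + dx / (METRES_PER_DEG_LAT *
                                            math.cos(math.radians(lat[i])))
            real[regime] += 60.0
            i += 1
    t = np.arange(n_fix) * 60.0
    return GpsSeries(t, lat, lon, labels)


# ---------------------------------------------------------------------------
# Benchmark bundle


def make_benchmark_suite(seed: int, out_dir,
                         acc_train_s: float = 1800.0,
                         acc_test_s: float = 3600.0,
                         gps_s: float = 6 * 3600.0) -> dict:
    """Write a versioned, fully reproducible end-to-end input bundle.

    Contents: gull-like acceleration train/test CSVs, a shearwater-like
    GPS CSV, the default feature catalogues and a run configuration.
    Regenerating with the same seed and version is bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    train_seed, test_seed, gps_seed = (int(s.integers(2**31)) for s in root.spawn(3))
    files = {}
    train = make_gull_series(acc_train_s, train_seed)
    test = make_gull_series(acc_test_s, test_seed)
    gps = make_gps_track(total_s=gps_s, seed=gps_seed)
    train.to_csv(out / "acc_train.csv")
    test.to_csv(out / "acc_test.csv")
    gps.to_csv(out / "gps.csv")
    default_acc_catalogue().to_yaml(out / "catalogue_acc.yml")
    default_gps_catalogue().to_yaml(out / "catalogue_gps.yml")
    RunConfig(seed=seed).to_yaml(out / "run_config.yml")
    manifest = {
        "bundle": "aioa-benchmark-suite",
        "version": SUITE_VERSION,
        "seed": int(seed),
        "files": ["acc_train.csv", "acc_test.csv", "gps.csv",
                  "catalogue_acc.yml", "catalogue_gps.yml", "run_config.yml"],
        "durations_s": {"acc_train": acc_train_s, "acc_test": acc_test_s,
                        "gps": gps_s},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files["manifest"] = manifest
    return manifest
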