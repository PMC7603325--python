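"""Camera-trigger state machines, battery model and deployment simulator.

Two consecutive-detection schemes suppress sporadic false positives:

* **Gull (accelerometer) trigger** — foraging dips are only detectable
  sporadically, so the machine first requires five consecutive 1-s windows
  classified as flying to become ARMED; while armed, a single foraging
  detection starts the camera immediately, and ten consecutive stationary
  windows disarm it.
* **ARS (GPS) trigger** — area-restricted search is detectable throughout
  its duration, so the camera starts after ``k`` (default 2) consecutive
  ARS classifications.

The battery model is calibrated to the hardware endpoints: a full charge
lasts 2 h of continuous video recording and 20 h of sensing only.  The
base (sensing) drain is therefore 1/20 of a charge per hour and video adds
1/2 − 1/20 per hour on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

ACTION_NONE = "none"
ACTION_START_VIDEO = "start_video"


@dataclass(frozen=True)
class GullTriggerConfig:
    arm_count: int = 5
    disarm_count: int = 10
    video_duration_s: float = 60.0
    startup_delay_s: float = 3.0

    def __post_init__(self):
        if self.arm_count < 1 or self.disarm_count < 1:
            raise ValidationError("arm_count and disarm_count must be >= 1")


@dataclass(frozen=True)
class ArsTriggerConfig:
    k: int = 2
    video_duration_s: float = 300.0
    startup_delay_s: float = 3.0

    def __post_init__(self):
        if self.k < 1:
            raise ValidationError("k must be >= 1")


@dataclass(frozen=True)
class GullTriggerState:
    armed: bool = False
    fly_count: int = 0
    stationary_count: int = 0


@dataclass(frozen=True)
class ArsTriggerState:
    ars_count: int = 0


def step_gull(state: GullTriggerState, prediction: str,
              config: GullTriggerConfig) -> tuple[GullTriggerState, str]:
    """One 1-s window through the gull machine; returns (state, action)."""
    if prediction not in ("stationary", "flying", "foraging"):
        raise ValidationError(f"unknown behaviour {prediction!r}")
    if not state.armed:
        if prediction == "flying":
            fly = state.fly_count + 1
            if fly >= config.arm_count:
                return GullTriggerState(armed=True), ACTION_NONE
            return GullTriggerState(fly_count=fly), ACTION_NONE
        return GullTriggerState(), ACTION_NONE
    # ARMED
    if prediction == "foraging":
        return GullTriggerState(armed=True), ACTION_START_VIDEO
    if prediction == "stationary":
        stat = state.stationary_count + 1
        if stat >= config.disarm_count:
            return GullTriggerState(), ACTION_NONE
        return GullTriggerState(armed=True, stationary_count=stat), ACTION_NONE
    # flying keeps the armed state and resets the disarm counter
    return GullTriggerState(armed=True), ACTION_NONE


def step_ars(state: ArsTriggerState, prediction: str,
             config: ArsTriggerConfig) -> tuple[ArsTriggerState, str]:
    """One GPS window through the consecutive-detection machine."""
    if prediction not in ("stationary", "transit", "ARS"):
        raise ValidationError(f"unknown behaviour {prediction!r}")
    if prediction != "ARS":
        return ArsTriggerState(), ACTION_NONE
    count = state.ars_count + 1
    if count >= config.k:
        return ArsTriggerState(), ACTION_START_VIDEO  # counter resets on firing
    return ArsTriggerState(ars_count=count), ACTION_NONE


def periodic_schedule(interval_s: float, video_duration_s: float,
                      total_s: float) -> list[tuple[float, float]]:
    """Naive baseline: camera events (start, end) at t = 0, interval, ...

    The first activation is at t = 0; a total shorter than one interval
    still yields that first event.
    """
    if interval_s <= video_duration_s:
        raise ValidationError("interval must exceed the video duration")
    if total_s <= 0:
        raise ValidationError("total time must be > 0")
    events = []
    t = 0.0
    while t < total_s:
        events.append((t, t + video_duration_s))
        t += interval_s
    return events


@dataclass
class BatteryModel:
    """Linear two-rate drain calibrated to full-charge endpoints.

    ``sensing_hours`` is the runtime with low-cost sensors only;
    ``video_hours`` the runtime under continuous video.  Fractional charge
    after t hours with v hours of camera-on time:
    ``1 - t/sensing_hours - v*(1/video_hours - 1/sensing_hours)``.
    """

    sensing_hours: float = 20.0
    video_hours: float = 2.0

    def __post_init__(self):
        if not (0 < self.video_hours <= self.sensing_hours):
            raise ValidationError("0 < video_hours <= sensing_hours required")
        self.base_rate = 1.0 / self.sensing_hours          # charge per hour
        self.video_extra_rate = 1.0 / self.video_hours - self.base_rate

    def charge_at(self, t_s: float, video_on_s: float) -> float:
        return 1.0 - (self.base_rate * t_s
                      + self.video_extra_rate * video_on_s) / 3600.0

    def exhaustion_time(self, video_fraction: float = 0.0) -> float:
        """Runtime in seconds when the camera is on a fixed fraction of time."""
        rate = self.base_rate + self.video_extra_rate * video_fraction
        return 3600.0 / rate


@dataclass
class DeploymentLog:
    """Per-window record of one simulated deployment."""

    window_s: float
    predictions: np.ndarray
    states: list
    camera_on: np.ndarray            # camera recording overlaps the window
    battery: np.ndarray              # charge at the *end* of each window
    camera_events: list[tuple[float, float, float]]  # (request, start, end)
    runtime_s: float
    truth: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.predictions)

    @property
    def camera_seconds(self) -> float:
        return float(sum(e - s for _, s, e in self.camera_events))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "window": np.arange(len(self.predictions)),
            "time_s": np.arange(len(self.predictions)) * self.window_s,
            "prediction": self.predictions,
            "camera_on": self.camera_on.astype(int),
            "battery": self.battery,
        })
        if self.truth is not None:
            df["label"] = self.truth
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def _overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def run_deployment(predictions, trigger, battery: BatteryModel | None = None,
                   window_s: float = 1.0, truth=None,
                   periodic: list[tuple[float, float]] | None = None,
                   force_video: bool = False) -> DeploymentLog:
    """Simulate a deployment over a stream of per-window classifications.

    ``predictions`` is the per-window classifier output (use
    :func:`aioa.trees.CostedTree.predict_table` upstream); ``trigger`` is a
    :class:`GullTriggerConfig` or :class:`ArsTriggerConfig` (ignored when a
    ``periodic`` schedule or ``force_video`` is given).  Camera actions are
    applied with the configured start-up delay; start requests during an
    active recording are ignored; the simulation halts when the battery is
    exhausted, truncating any recording in progress.
    """
    battery = battery if battery is not None else BatteryModel()
    predictions = np.asarray(predictions, dtype=object)
    n = len(predictions)
    if truth is not None and len(truth) != n:
        raise ValidationError("truth labels and prediction stream disagree in length")

    if isinstance(trigger, GullTriggerConfig):
        state, step = GullTriggerState(), step_gull
        duration, delay = trigger.video_duration_s, trigger.startup_delay_s
    elif isinstance(trigger, ArsTriggerConfig):
        state, step = ArsTriggerState(), step_ars
        duration, delay = trigger.video_duration_s, trigger.startup_delay_s
    elif trigger is None and (periodic is not None or force_video):
        state, step, duration, delay = None, None, 0.0, 0.0
    else:
        raise ValidationError(f"unsupported trigger {trigger!r}")

    events: list[tuple[float, float, float]] = []  # request, start, end
    if periodic is not None:
        events = [(s, s, e) for s, e in periodic]
    if force_video:
        events = [(0.0, 0.0, n * window_s)]

    states = []
    camera_on = np.zeros(n, dtype=bool)
    charge = np.ones(n)
    video_on_cum = 0.0
    current_end = -np.inf  # end of the active/last recording
    runtime = n * window_s
    halted_at = None

    for i in range(n):
        t0 = i * window_s
        t1 = t0 + window_s
        if step is not None:
            state, action = step(state, predictions[i], trigger)
            states.append(state)
            if action == ACTION_START_VIDEO and t0 >= current_end:
                start = t0 + delay
                events.append((t0, start, start + duration))
                current_end = start + duration
        # battery accounting over [t0, t1)
        vo = sum(_overlap(t0, t1, s, e) for _, s, e in events)
        video_on_cum += vo
        c = battery.charge_at(t1, video_on_cum)
        charge[i] = max(c, 0.0)
        camera_on[i] = vo > 0.0
        if c <= 0.0:
            # solve the exact exhaustion time within this window
            c0 = battery.charge_at(t0, video_on_cum - vo)
            rate = (c0 - c) / window_s  # charge per second over this window
            halted_at = t0 + (c0 / rate if rate > 0 else 0.0)
            n_used = i + 1
            states = states[:n_used] if step is not None else states
            predictions = predictions[:n_used]
            camera_on = camera_on[:n_used]
            charge = charge[:n_used]
            truth = truth[:n_used] if truth is not None else None
            runtime = halted_at
            break

    # truncate recordings to the realized runtime
    events = [(r, s, min(e, runtime)) for r, s, e in events if s < runtime]
    events.sort(key=lambda x: x[1])
    return DeploymentLog(window_s, predictions, states, camera_on, charge,
                         events, runtime, None if truth is None
                         else np.asarray(truth, dtype=object))
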