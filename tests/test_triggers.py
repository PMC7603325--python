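"""Trigger state machines, periodic baseline, battery and deployment sim."""

import itertools

import numpy as np
import pytest

from aioa.errors import ValidationError
from aioa.triggers import (
    ACTION_NONE,
    ACTION_START_VIDEO,
    ArsTriggerConfig,
    ArsTriggerState,
    BatteryModel,
    GullTriggerConfig,
    GullTriggerState,
    periodic_schedule,
    run_deployment,
    step_ars,
    step_gull,
)


def run_gull(seq, config=None):
    config = config or GullTriggerConfig()
    state = GullTriggerState()
    actions = []
    for p in seq:
        state, a = step_gull(state, p, config)
        actions.append(a)
    return actions


def run_ars(seq, config=None):
    config = config or ArsTriggerConfig()
    state = ArsTriggerState()
    actions = []
    for p in seq:
        state, a = step_ars(state, p, config)
        actions.append(a)
    return actions


F, S, G = "flying", "stationary", "foraging"


class TestGullMachine:
    def test_five_flying_then_foraging_fires(self):
        actions = run_gull([F, F, F, F, F, G])
        assert actions[-1] == ACTION_START_VIDEO
        assert all(a == ACTION_NONE for a in actions[:-1])

    def test_four_flying_then_foraging_does_not_fire(self):
        assert ACTION_START_VIDEO not in run_gull([F, F, F, F, G])

    def test_foraging_resets_arm_counter_while_searching(self):
        # the interrupted run of flying never reaches five consecutive
        assert ACTION_START_VIDEO not in run_gull([F, F, G, F, F, F, G])

    def test_ten_stationary_disarms(self):
        seq = [F] * 5 + [S] * 10 + [G]
        assert ACTION_START_VIDEO not in run_gull(seq)

    def test_nine_stationary_does_not_disarm(self):
        seq = [F] * 5 + [S] * 9 + [G]
        assert run_gull(seq)[-1] == ACTION_START_VIDEO

    def test_flying_resets_disarm_counter(self):
        seq = [F] * 5 + [S] * 9 + [F] + [S] * 9 + [G]
        assert run_gull(seq)[-1] == ACTION_START_VIDEO

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            step_gull(GullTriggerState(), "ARS", GullTriggerConfig())

    def test_exhaustive_short_traces_match_oracle(self):
        """All prediction sequences of length <= 8 vs a hand-written oracle."""
        config = GullTriggerConfig(arm_count=5, disarm_count=10)

        def oracle(seq):
            armed, fly, stat = False, 0, 0
            out = []
            for p in seq:
                action = ACTION_NONE
                if not armed:
                    fly = fly + 1 if p == F else 0
                    if fly >= 5:
                        armed, fly, stat = True, 0, 0
                else:
                    if p == G:
                        action = ACTION_START_VIDEO
                        stat = 0
                    elif p == S:
                        stat += 1
                        if stat >= 10:
                            armed, fly, stat = False, 0, 0
                    else:
                        stat = 0
                out.append(action)
            return out

        for n in range(1, 9):
            for seq in itertools.product([F, S, G], repeat=n):
                assert run_gull(list(seq), config) == oracle(seq), seq


A, T = "ARS", "transit"


class TestArsMachine:
    def test_two_consecutive_ars_fire(self):
        assert run_ars([A, A]) == [ACTION_NONE, ACTION_START_VIDEO]

    def test_interrupted_ars_does_not_fire(self):
        assert ACTION_START_VIDEO not in run_ars([A, T, A])

    def test_k_one_fires_immediately(self):
        assert run_ars([A], ArsTriggerConfig(k=1))[0] == ACTION_START_VIDEO

    def test_counter_resets_after_firing(self):
        actions = run_ars([A, A, A])
        assert actions == [ACTION_NONE, ACTION_START_VIDEO, ACTION_NONE]

    def test_exhaustive_short_traces_match_oracle(self):
        config = ArsTriggerConfig(k=2)

        def oracle(seq):
            count, out = 0, []
            for p in seq:
                if p == A:
                    count += 1
                    if count >= 2:
                        out.append(ACTION_START_VIDEO)
                        count = 0
                    else:
                        out.append(ACTION_NONE)
                else:
                    count = 0
                    out.append(ACTION_NONE)
            return out

        for n in range(1, 9):
            for seq in itertools.product([A, T, "stationary"], repeat=n):
                assert run_ars(list(seq), config) == oracle(seq), seq


class TestPeriodicSchedule:
    def test_hourly_count_with_15min_interval(self):
        assert len(periodic_schedule(900, 60, 3600)) == 4

    def test_single_interval(self):
        events = periodic_schedule(1800, 300, 1800)
        assert events == [(0.0, 300.0)]

    def test_short_total_still_first_event(self):
        assert len(periodic_schedule(1800, 300, 600)) == 1

    def test_interval_not_longer_than_video_rejected(self):
        with pytest.raises(ValidationError):
            periodic_schedule(60, 60, 3600)


class TestBatteryAndDeployment:
    def test_sensing_only_runtime_is_twenty_hours(self):
        preds = np.full(20 * 3600 + 50, "stationary", dtype=object)
        log = run_deployment(preds, GullTriggerConfig(), BatteryModel())
        assert log.runtime_s / 3600 == pytest.approx(20.0, abs=1e-9)
        assert len(log.camera_events) == 0

    def test_continuous_video_runtime_is_two_hours(self):
        preds = np.full(2 * 3600 + 50, "stationary", dtype=object)
        log = run_deployment(preds, None, BatteryModel(), force_video=True)
        assert log.runtime_s / 3600 == pytest.approx(2.0, abs=1e-9)

    def test_single_burst_yields_one_delayed_video(self):
        """Hand-traced: armed by 5 flying windows, foraging at window 5
        requests the camera; recording spans [t+3, t+63)."""
        preds = np.array([F] * 5 + [G] + [F] * 200, dtype=object)
        log = run_deployment(preds, GullTriggerConfig(), BatteryModel())
        assert len(log.camera_events) == 1
        req, start, end = log.camera_events[0]
        assert (req, start, end) == (5.0, 8.0, 68.0)
        assert log.camera_seconds == 60.0

    def test_requests_during_recording_ignored(self):
        preds = np.array([F] * 5 + [G] * 100, dtype=object)
        log = run_deployment(preds, GullTriggerConfig(), BatteryModel())
        # second video may only start after the first ends
        starts = [s for _, s, _ in log.camera_events]
        ends = [e for _, _, e in log.camera_events]
        assert all(s2 >= e1 for e1, s2 in zip(ends, starts[1:]))
        assert len(log.camera_events) == 2  # 105 s stream fits two requests

    def test_battery_monotone_and_matches_closed_form(self):
        preds = np.array([F] * 5 + [G] + [F] * 500, dtype=object)
        bm = BatteryModel()
        log = run_deployment(preds, GullTriggerConfig(), bm)
        assert np.all(np.diff(log.battery) <= 1e-15)
        t = len(log) * 1.0
        expected = 1.0 - (bm.base_rate * t
                          + bm.video_extra_rate * log.camera_seconds) / 3600.0
        assert log.battery[-1] == pytest.approx(expected, abs=1e-9)

    def test_triggered_beats_continuous_on_runtime_and_camera_hours(self):
        preds = np.array(([F] * 5 + [G] + [S] * 200) * 40, dtype=object)
        bm = BatteryModel()
        log = run_deployment(preds, GullTriggerConfig(), bm)
        cont = run_deployment(preds, None, bm, force_video=True)
        assert log.camera_seconds < cont.camera_seconds
        assert log.runtime_s >= cont.runtime_s

    def test_no_video_without_prior_arming_sequence(self, rng):
        """Property: every video request is preceded by >= 5 consecutive
        flying windows with no disarm in between."""
        preds = rng.choice([F, S, G], size=2000, p=[0.3, 0.55, 0.15])
        log = run_deployment(preds.astype(object), GullTriggerConfig(),
                             BatteryModel())
        for req, _, _ in log.camera_events:
            i = int(req)
            # scan backwards: must find 5 consecutive F before 10 consecutive S
            ok, run, stat = False, 0, 0
            for j in range(i - 1, -1, -1):
                if preds[j] == F:
                    run += 1
                    stat = 0
                    if run >= 5:
                        ok = True
                        break
                elif preds[j] == S:
                    stat += 1
                    run = 0
                    if stat >= 10:
                        break
                else:  # foraging: breaks both the flying run and the S streak
                    run = 0
                    stat = 0
            assert ok
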