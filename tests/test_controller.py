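"""Posture FSM, command planning, the simulated plant and the closed loop."""

import numpy as np
import pytest

from halluxgrip.controller import (
    ControlCommand,
    DistanceLevelMap,
    HandState,
    map_presses,
    plan_command,
    run_closed_loop,
    step_plant,
)
from halluxgrip.filters import FilterParams, filter_trace
from halluxgrip.posture import opening_time, predict_ratio
from halluxgrip.press_detect import calibrate_threshold
from halluxgrip.scenarios import drink_water_trace, standing_press_trace
from halluxgrip.simulate import GaitSpec, PressSchedule, default_channel_specs, generate_trace

OPEN_STATE = HandState(openness=50.0, phase="open")
CLOSED = HandState()


class TestMapPresses:
    @pytest.mark.parametrize(
        "S, state, expected",
        [
            (1, CLOSED, 25.0),
            (2, CLOSED, 50.0),
            (3, CLOSED, 75.0),
            (4, CLOSED, 100.0),
            (7, CLOSED, 100.0),  # saturates at the widest code level
            (0, OPEN_STATE, 0.0),  # a quiet window closes an open hand
            (0, CLOSED, None),  # ... and leaves a closed hand alone
        ],
    )
    def test_five_level_code(self, S, state, expected):
        assert map_presses(S, state, DistanceLevelMap()) == expected

    def test_level_map_must_be_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            DistanceLevelMap({1: 50.0, 2: 25.0, 3: 75.0, 4: 100.0})

    def test_level_map_must_reach_full_open(self):
        with pytest.raises(ValueError, match="100"):
            DistanceLevelMap({1: 25.0, 2: 50.0})


class TestPlanCommand:
    def test_already_at_target_holds(self, quartic_model):
        cmd = plan_command(CLOSED, 0.0, quartic_model)
        assert (cmd.line_A, cmd.line_B, cmd.duration) == ("low", "low", 0.0)

    def test_full_open_duration_from_calibration(self, quartic_model):
        cmd = plan_command(CLOSED, 100.0, quartic_model, t_A=2.0)
        expected = 2.0 * (
            predict_ratio(quartic_model, 100.0) - predict_ratio(quartic_model, 0.0)
        )
        assert cmd.action == "open"
        assert cmd.duration == pytest.approx(expected, abs=0.011)

    def test_closing_has_positive_duration(self, quartic_model):
        cmd = plan_command(HandState(100.0, "open"), 0.0, quartic_model)
        assert cmd.action == "close"
        assert cmd.duration > 0

    def test_target_out_of_range_rejected(self, quartic_model):
        with pytest.raises(ValueError, match="target"):
            plan_command(CLOSED, 101.0, quartic_model)

    def test_forbidden_line_combination_unconstructible(self):
        with pytest.raises(ValueError, match="high"):
            ControlCommand("high", "high", 1.0)
        with pytest.raises(ValueError, match="high"):
            HandState(openness=10.0, phase="open", line_A="high", line_B="high")


class TestStepPlant:
    def test_hold_leaves_state_unchanged(self, quartic_model):
        state = HandState(30.0, "open")
        new = step_plant(state, ControlCommand("low", "low", 5.0), quartic_model)
        assert new.openness == state.openness

    @pytest.mark.parametrize("target", [25.0, 50.0, 75.0, 100.0])
    def test_plan_then_step_reaches_target(self, quartic_model, target):
        cmd = plan_command(CLOSED, target, quartic_model)
        new = step_plant(CLOSED, cmd, quartic_model)
        assert new.openness == pytest.approx(target, abs=2.0)

    def test_full_open_command_saturates_at_span(self, quartic_model):
        cmd = ControlCommand("high", "low", 2.0)
        new = step_plant(CLOSED, cmd, quartic_model, t_A=2.0)
        assert new.openness == 100.0

    def test_round_trip_open_close(self, quartic_model):
        opened = step_plant(CLOSED, plan_command(CLOSED, 75.0, quartic_model), quartic_model)
        closed = step_plant(opened, plan_command(opened, 0.0, quartic_model), quartic_model)
        assert closed.openness == pytest.approx(0.0, abs=2.0)
        assert closed.phase == "closed"


class TestClosedLoop:
    def _calib_for(self, trace, calibration_s=3.0):
        filtered = filter_trace(trace, "hallux", FilterParams())
        n = int(calibration_s * trace.sampling_rate)
        return calibrate_threshold(filtered[:n], 1.1)

    def test_drink_water_two_openings_two_closings(self, quartic_model):
        trace = drink_water_trace(seed=3)
        log = run_closed_loop(trace, self._calib_for(trace), quartic_model)
        actions = [e.command.action for e in log]
        assert actions.count("open") == 2
        assert actions.count("close") == 2
        assert sum(e.S for e in log) == 2

    def test_press_free_trace_leaves_hand_closed(self, quartic_model):
        trace = standing_press_trace(0, seed=12)
        log = run_closed_loop(trace, self._calib_for(trace), quartic_model)
        assert log == []

    def test_press_pattern_maps_to_coded_targets(self, quartic_model):
        """Windows with (1, 0, 3, 0) presses command (25, 0, 75, 0) mm.

        A 6 s scan window fits three deliberate presses at the cadence the
        filter can resolve.
        """
        b = 6.0
        times = [2 * b + 0.3] + [4 * b + 0.3 + 1.2 * j for j in range(3)]
        trace = generate_trace(
            GaitSpec("standing"), default_channel_specs(),
            PressSchedule([(t, 0.3, "hallux") for t in times]),
            duration=6 * b, seed=13,
        )
        calib = self._calib_for(trace, calibration_s=2 * b)
        log = run_closed_loop(trace, calib, quartic_model, scan_time_b=b)
        assert [e.target for e in log] == [25.0, 0.0, 75.0, 0.0]

    def test_replay_determinism(self, quartic_model):
        trace = drink_water_trace(seed=5)
        calib = self._calib_for(trace)
        first = run_closed_loop(trace, calib, quartic_model)
        second = run_closed_loop(trace, calib, quartic_model)
        assert first == second

    def test_no_forbidden_line_combination_in_logs(self, quartic_model):
        trace = standing_press_trace(5, seed=14)
        log = run_closed_loop(trace, self._calib_for(trace), quartic_model)
        assert log, "expected at least one actuation"
        for e in log:
            assert (e.command.line_A, e.command.line_B) != ("high", "high")

    def test_level_accuracy_across_seeded_scenarios(self, quartic_model):
        """After every open command the plant sits within 2 mm of the coded level."""
        errors = []
        for seed in range(200):
            k = 1 + seed % 4
            trace = standing_press_trace(k, seed=seed, spacing=1.2, duration=12.0)
            log = run_closed_loop(trace, self._calib_for(trace), quartic_model)
            for e in log:
                if e.command.action == "open":
                    errors.append(abs(e.state.openness - e.target))
        assert errors, "expected open commands in the scenario batch"
        assert max(errors) <= 2.0
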