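"""Press-count -> posture finite-state machine and a simulated hand plant.

The hand is driven by two lines: (A high, B low) opens, (A low, B high)
closes, (low, low) holds.  (high, high) is undefined and never emitted.
Press counts decoded per scan window select one of five interfinger
distances (0, 25, 50, 75, 100 mm): one press opens to 25 mm, two to 50,
three to 75, four-or-more to 100, and a window with no press while the
hand is open closes it.  Command durations come from the fitted
time-ratio calibration: moving between distances l0 and l1 takes
|d(l1) - d(l0)| x t_A on either line.

The plant simulated here integrates openness along the inverse of the
fitted time-ratio curve, i.e. it is the idealised hand the calibration
describes; closing is assumed to traverse the same curve as opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .filters import FilterParams
from .posture import DEFAULT_T_A, FULL_OPEN_MM, PostureModel, opening_time, predict_ratio
from .press_detect import (
    DEFAULT_SCAN_TIME_B,
    MAX_PRESS_LEVEL,
    CalibrationResult,
    PressCountResult,
    stream_windows,
)
from .simulate import ForceTrace

__all__ = [
    "COMMAND_TICK_S",
    "HandState",
    "DistanceLevelMap",
    "ControlCommand",
    "LogEvent",
    "map_presses",
    "plan_command",
    "step_plant",
    "run_closed_loop",
]

COMMAND_TICK_S = 0.01  # command durations are quantized to this tick


@dataclass(frozen=True)
class HandState:
    """Hand openness in mm plus the current line levels."""

    openness: float = 0.0
    phase: str = "closed"
    line_A: str = "low"
    line_B: str = "low"

    def __post_init__(self) -> None:
        if not 0.0 <= self.openness <= FULL_OPEN_MM:
            raise ValueError(f"openness must lie in [0, {FULL_OPEN_MM}] mm")
        if self.phase not in ("open", "closed", "moving"):
            raise ValueError("phase must be open, closed or moving")
        if self.phase == "closed" and self.openness != 0.0:
            raise ValueError("phase 'closed' requires openness = 0")
        if self.line_A == "high" and self.line_B == "high":
            raise ValueError("line_A and line_B may never both be high")


@dataclass(frozen=True)
class DistanceLevelMap:
    """Press count -> target distance; the five-level posture code."""

    levels: Mapping[int, float] = field(
        default_factory=lambda: {1: 25.0, 2: 50.0, 3: 75.0, 4: 100.0}
    )

    def __post_init__(self) -> None:
        counts = sorted(self.levels)
        if counts != list(range(1, len(counts) + 1)):
            raise ValueError("levels must be keyed 1..K consecutively")
        values = [self.levels[c] for c in counts]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("levels must be strictly increasing in press count")
        if values[-1] != FULL_OPEN_MM:
            raise ValueError(f"largest level must be {FULL_OPEN_MM} mm (full open)")

    @property
    def max_count(self) -> int:
        return max(self.levels)

    def target_for(self, presses: int) -> float:
        return float(self.levels[min(presses, self.max_count)])


@dataclass(frozen=True)
class ControlCommand:
    """Line levels held for a duration: (high,low)=open, (low,high)=close, (low,low)=hold."""

    line_A: str
    line_B: str
    duration: float

    def __post_init__(self) -> None:
        if self.line_A == "high" and self.line_B == "high":
            raise ValueError("(high, high) is undefined and must never be emitted")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def action(self) -> str:
        if self.line_A == "high":
            return "open"
        if self.line_B == "high":
            return "close"
        return "hold"


def map_presses(S: int, state: HandState, level_map: DistanceLevelMap) -> float | None:
    """Target openness for a window's press count; None means no action.

    One or more presses select the coded distance (counts above the top
    level saturate at full open).  Zero presses close an open hand and do
    nothing to a closed one.
    """
    if S < 0:
        raise ValueError("S must be >= 0")
    if S >= 1:
        return level_map.target_for(S)
    if state.openness > 0.0:
        return 0.0
    return None


def plan_command(
    current: HandState,
    target: float,
    model: PostureModel,
    t_A: float = DEFAULT_T_A,
    tick: float = COMMAND_TICK_S,
) -> ControlCommand:
    """Line command whose duration moves the hand from its openness to target.

    The duration is the difference of calibrated drive times,
    |t_open(target) - t_open(current)|, quantized to the command tick.
    """
    if not 0.0 <= target <= FULL_OPEN_MM:
        raise ValueError(f"target must lie in [0, {FULL_OPEN_MM}] mm")
    dt = opening_time(model, target, t_A) - opening_time(model, current.openness, t_A)
    if dt > 0:
        lines = ("high", "low")
    elif dt < 0:
        lines = ("low", "high")
    else:
        return ControlCommand("low", "low", 0.0)
    duration = round(abs(dt) / tick) * tick
    return ControlCommand(lines[0], lines[1], duration)


def _invert_ratio(model: PostureModel, d: float) -> float:
    """Distance whose fitted time ratio is d, via a monotone grid inverse."""
    grid = np.linspace(0.0, FULL_OPEN_MM, 2001)
    ratios = np.maximum.accumulate(predict_ratio(model, grid))
    if d <= ratios[0]:
        return 0.0
    if d >= ratios[-1]:
        return FULL_OPEN_MM
    return float(np.interp(d, ratios, grid))


def step_plant(
    state: HandState,
    cmd: ControlCommand,
    model: PostureModel,
    t_A: float = DEFAULT_T_A,
) -> HandState:
    """Advance the simulated hand by one command.

    Opening for a duration tau advances the time ratio by tau / t_A and the
    new openness is the calibrated curve's inverse at that ratio (clamped
    to the hand's span); closing runs the same curve backwards.
    """
    if cmd.action == "hold" or cmd.duration == 0.0:
        return replace(state, line_A="low", line_B="low")
    d0 = float(predict_ratio(model, state.openness))
    delta = cmd.duration / t_A
    d1 = d0 + delta if cmd.action == "open" else d0 - delta
    openness = _invert_ratio(model, d1)
    openness = min(max(openness, 0.0), FULL_OPEN_MM)
    phase = "closed" if openness == 0.0 else "open"
    return HandState(openness=openness, phase=phase, line_A="low", line_B="low")


@dataclass(frozen=True)
class LogEvent:
    """One actuated scan window of the closed loop."""

    window_index: int
    S: int
    target: float
    command: ControlCommand
    state: HandState


def run_closed_loop(
    trace: ForceTrace,
    calib: CalibrationResult,
    model: PostureModel,
    level_map: DistanceLevelMap | None = None,
    scan_time_b: float = DEFAULT_SCAN_TIME_B,
    filter_params: FilterParams = FilterParams(),
    t_A: float = DEFAULT_T_A,
    channel: str = "hallux",
) -> list[LogEvent]:
    """Replay a trace through press decoding and the posture FSM.

    Each scan window's press count is capped at the top code level, mapped
    to a target distance, planned as a line command and applied to the
    simulated plant.  Windows that require no action (closed hand, no
    press) produce no event; the log is fully determined by the inputs.
    """
    level_map = level_map or DistanceLevelMap()
    state = HandState()
    log: list[LogEvent] = []
    for i, window in enumerate(
        stream_windows(trace, channel, calib, scan_time_b, filter_params)
    ):
        S = min(window.S, MAX_PRESS_LEVEL)
        target = map_presses(S, state, level_map)
        if target is None:
            continue
        cmd = plan_command(state, target, model, t_A)
        state = step_plant(state, cmd, model, t_A)
        log.append(LogEvent(window_index=i, S=S, target=target, command=cmd, state=state))
    return log
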