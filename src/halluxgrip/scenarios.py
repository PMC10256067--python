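"""Choreographed daily-activity traces for closed-loop demos.

Each scenario builds a standing-regime trace whose press schedule encodes
the toe actions a user would perform for that activity, with a press-free
first scan window so the pipeline can calibrate its threshold from the
trace itself.  Presses are placed early within their scan windows so that
the filter group delay keeps each decoded peak inside the intended window.
"""

from __future__ import annotations

from .press_detect import DEFAULT_SCAN_TIME_B
from .simulate import (
    DEFAULT_SAMPLING_RATE,
    ForceTrace,
    GaitSpec,
    PressSchedule,
    default_channel_specs,
    generate_trace,
)

__all__ = [
    "SCENARIOS",
    "build_scenario",
    "drink_water_trace",
    "tie_shoelaces_trace",
    "standing_press_trace",
]

PRESS_DURATION_S = 0.3


def _press_times_to_schedule(times: list[float]) -> PressSchedule:
    return PressSchedule([(t, PRESS_DURATION_S, "hallux") for t in times])


def drink_water_trace(
    seed: int = 0,
    scan_time_b: float = DEFAULT_SCAN_TIME_B,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> ForceTrace:
    """One-time grasp: open to grab the cup, drink, open again to release.

    The user presses the insole twice in total — once per hand opening —
    with press-free windows in between that close the hand around the cup
    and after release.  Window sequence: two calibration windows, press
    (open), quiet (close on cup), press (open/release), quiet (close).
    """
    b = scan_time_b
    times = [2.0 * b + 0.3, 4.0 * b + 0.3]
    return generate_trace(
        gait=GaitSpec("standing"),
        specs=default_channel_specs(),
        presses=_press_times_to_schedule(times),
        duration=6.0 * b,
        sampling_rate=sampling_rate,
        seed=seed,
    )


def tie_shoelaces_trace(
    seed: int = 0,
    scan_time_b: float = DEFAULT_SCAN_TIME_B,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> ForceTrace:
    """Continuous fine task: four single presses, one per lace manoeuvre,
    each followed by a quiet window that closes the grip on the lace."""
    b = scan_time_b
    times = [k * b + 0.3 for k in (2, 4, 6, 8)]
    return generate_trace(
        gait=GaitSpec("standing"),
        specs=default_channel_specs(),
        presses=_press_times_to_schedule(times),
        duration=10.0 * b,
        sampling_rate=sampling_rate,
        seed=seed,
    )


def standing_press_trace(
    n_presses: int,
    seed: int,
    spacing: float = 1.2,
    press_duration: float = PRESS_DURATION_S,
    calibration_s: float = 3.0,
    duration: float = 12.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> ForceTrace:
    """Standing trace with n deliberate hallux presses after a press-free preamble.

    Presses are spaced 1.2 s apart — the deliberate-press cadence the
    smoothing filter can resolve at its default bandwidth — and start just
    after the calibration preamble.
    """
    times = [calibration_s + 0.3 + spacing * j for j in range(n_presses)]
    return generate_trace(
        gait=GaitSpec("standing"),
        specs=default_channel_specs(),
        presses=PressSchedule([(t, press_duration, "hallux") for t in times]),
        duration=duration,
        sampling_rate=sampling_rate,
        seed=seed,
    )


SCENARIOS = {
    "drink-water": drink_water_trace,
    "tie-shoelaces": tie_shoelaces_trace,
}


def build_scenario(name: str, seed: int = 0, **kwargs) -> ForceTrace:
    try:
        factory = SCENARIOS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}") from None
    return factory(seed=seed, **kwargs)
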