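"""Threshold calibration and press counting on the filtered hallux channel.

A deliberate toe press drives the filtered contact force above a per-user
threshold and back down, producing exactly two threshold crossings.  The
press count in a scan window is therefore half the number of sign changes
of (a_i - t): S = sum g((a_{i-1}-t)(a_i-t)) / 2 with g(x)=1 for x<0 and 0
otherwise.  The threshold is calibrated from a press-free segment (walking,
standing or sitting) as a safety margin above its maximum, which shields
gait peaks and incidental toe contact from being counted as presses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .filters import FilterParams, filter_trace
from .simulate import ForceTrace

__all__ = [
    "CalibrationResult",
    "ScanWindow",
    "PressCountResult",
    "calibrate_threshold",
    "count_presses",
    "stream_windows",
]

DEFAULT_SCAN_TIME_B = 1.5  # s; shortest acquisition period per decoding cycle
DEFAULT_MARGIN_FACTOR = 1.1
MAX_PRESS_LEVEL = 4  # 4-or-more presses all map to the widest opening


@dataclass(frozen=True)
class CalibrationResult:
    """Per-user force threshold t and the press-free segment it came from."""

    threshold_t: float
    source_window: tuple[float, float] = (0.0, 0.0)
    source_regime: str = "standing"
    margin_factor: float = DEFAULT_MARGIN_FACTOR

    def __post_init__(self) -> None:
        if self.threshold_t <= 0:
            raise ValueError("threshold_t must be > 0")
        if self.source_regime not in ("walking", "standing", "sitting"):
            raise ValueError("source_regime must be walking, standing or sitting")


@dataclass(frozen=True)
class ScanWindow:
    scan_time_b: float  # s
    samples_N: int

    def __post_init__(self) -> None:
        if self.scan_time_b <= 0:
            raise ValueError("scan_time_b must be > 0")
        if self.samples_N < 1:
            raise ValueError("samples_N must be >= 1")


@dataclass(frozen=True)
class PressCountResult:
    """Press count S for one scan window plus the crossings that produced it."""

    S: int
    threshold_t: float
    window: ScanWindow | None = None
    crossing_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError("S must be >= 0")


def calibrate_threshold(
    baseline: Sequence[float] | np.ndarray,
    margin_factor: float = DEFAULT_MARGIN_FACTOR,
    source_regime: str = "standing",
    source_window: tuple[float, float] | None = None,
) -> CalibrationResult:
    """Threshold = margin_factor x max(press-free baseline segment).

    The margin keeps the threshold conservative so weight shifts and gait
    peaks never register as presses.  An all-zero baseline is rejected: an
    unloaded sensor carries no information about the user's resting force.
    """
    x = np.asarray(baseline, dtype=float)
    if x.size == 0:
        raise ValueError("baseline must be non-empty")
    if margin_factor < 1.0:
        raise ValueError("margin_factor must be >= 1")
    peak = float(np.max(x))
    if peak <= 0.0:
        raise ValueError("baseline maximum must be positive (unloaded sensor)")
    return CalibrationResult(
        threshold_t=margin_factor * peak,
        source_window=source_window or (0.0, x.size and float(x.size)),
        source_regime=source_regime,
        margin_factor=margin_factor,
    )


def _crossings(a: np.ndarray, t: float) -> np.ndarray:
    """Indices i where (a_{i-1}-t)(a_i-t) < 0, i.e. strict sign changes about t.

    Samples exactly equal to t give a zero product, g(0)=0: tangential
    touches never count.
    """
    s = a - t
    return np.nonzero(s[:-1] * s[1:] < 0.0)[0] + 1


def count_presses(
    a: Sequence[float] | np.ndarray,
    t: float,
    window: ScanWindow | None = None,
) -> PressCountResult:
    """Count supra-threshold peaks in one window of filtered force values.

    Each completed peak contributes one up-crossing and one down-crossing;
    S is the crossing count halved (floor: an unfinished trailing
    half-crossing belongs to the next window, see stream_windows).
    """
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 samples to count crossings")
    idx = _crossings(a, t)
    return PressCountResult(
        S=len(idx) // 2,
        threshold_t=t,
        window=window,
        crossing_indices=tuple(int(i) for i in idx),
    )


def stream_windows(
    trace: ForceTrace,
    channel: str,
    calib: CalibrationResult,
    scan_time_b: float = DEFAULT_SCAN_TIME_B,
    filter_params: FilterParams = FilterParams(),
) -> list[PressCountResult]:
    """Partition a filtered channel into consecutive scan windows and count presses.

    Windows tile the stream without overlap (the last one may be shorter).
    A peak straddling a window boundary is attributed to the window in
    which it completes: the unpaired crossing carries over instead of
    being rounded, so nothing is double-counted or lost.
    """
    if scan_time_b <= 0:
        raise ValueError("scan_time_b must be > 0")
    filtered = filter_trace(trace, channel, filter_params)
    t = calib.threshold_t
    n_win = max(2, int(round(scan_time_b * trace.sampling_rate)))

    results: list[PressCountResult] = []
    # A stream that starts above threshold is a press already in progress.
    pending = 1 if filtered[0] > t else 0
    prev_sample: float | None = None
    for start in range(0, filtered.size, n_win):
        chunk = filtered[start : start + n_win]
        if prev_sample is None:
            seq = chunk
            offset = 0
        else:
            seq = np.concatenate(([prev_sample], chunk))
            offset = 1
        idx = _crossings(seq, t) - offset if seq.size >= 2 else np.array([], dtype=int)
        total = pending + len(idx)
        results.append(
            PressCountResult(
                S=total // 2,
                threshold_t=t,
                window=ScanWindow(scan_time_b=scan_time_b, samples_N=len(chunk)),
                crossing_indices=tuple(int(start + i) for i in idx),
            )
        )
        pending = total % 2
        prev_sample = float(chunk[-1])
    return results
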