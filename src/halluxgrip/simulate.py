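"""Synthetic smart-insole contact-force traces.

A flexible insole carries thin-film force sensors under four foot regions:
the hallux (big toe), the little toe, the forefoot and the heel.  During
walking the heel and forefoot channels show large periodic stance peaks,
while the toe channels show much smaller gait-coupled peaks; a deliberate
toe press adds a high, short-lived bump that clearly exceeds anything gait
produces on that channel.  This module generates multi-channel traces with
exactly that structure so the whole decoding pipeline can be exercised
without hardware.

Forces are dimensionless sensor counts on a nominal 0-2500 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "TOE_REGIONS",
    "ChannelSpec",
    "PressEvent",
    "PressSchedule",
    "GaitSpec",
    "ForceTrace",
    "TraceFormatError",
    "default_channel_specs",
    "generate_trace",
    "write_trace",
    "read_trace",
]

REGIONS = ("hallux", "little_toe", "forefoot", "heel")
TOE_REGIONS = ("hallux", "little_toe")

DEFAULT_SAMPLING_RATE = 100.0  # Hz


class TraceFormatError(ValueError):
    """Raised for malformed trace files (bad header, ragged rows, empty)."""


@dataclass(frozen=True)
class ChannelSpec:
    """Per-region signal parameters, in sensor counts.

    For toe regions the press amplitude must exceed the gait amplitude:
    the deliberate press has to be discriminable from gait interference,
    which is what makes the toe channels usable as a control site.
    """

    region: str
    baseline_force: float
    gait_peak_amplitude: float
    press_peak_amplitude: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        for name in ("baseline_force", "gait_peak_amplitude", "press_peak_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.region in TOE_REGIONS and not (
            self.press_peak_amplitude > self.gait_peak_amplitude
        ):
            raise ValueError(
                f"{self.region}: press_peak_amplitude must exceed gait_peak_amplitude"
            )


def default_channel_specs() -> list[ChannelSpec]:
    """Nominal channel parameters matching the 0-2500 count scale.

    Hallux presses reach ~2000 counts while walking only lifts the hallux
    to ~500; heel/forefoot stance peaks are large and similar to each other.
    """
    return [
        ChannelSpec("hallux", baseline_force=100.0, gait_peak_amplitude=500.0,
                    press_peak_amplitude=2000.0, noise_sd=30.0),
        ChannelSpec("little_toe", baseline_force=80.0, gait_peak_amplitude=400.0,
                    press_peak_amplitude=1500.0, noise_sd=30.0),
        ChannelSpec("forefoot", baseline_force=300.0, gait_peak_amplitude=1800.0,
                    press_peak_amplitude=2000.0, noise_sd=30.0),
        ChannelSpec("heel", baseline_force=300.0, gait_peak_amplitude=2000.0,
                    press_peak_amplitude=2000.0, noise_sd=30.0),
    ]


@dataclass(frozen=True)
class PressEvent:
    onset_time: float  # s
    duration: float  # s
    channel: str

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class PressSchedule:
    """Deliberate toe presses: non-overlapping per channel."""

    events: tuple[PressEvent, ...] = ()

    def __init__(self, events: Iterable[PressEvent | tuple] = ()) -> None:
        parsed = tuple(
            e if isinstance(e, PressEvent) else PressEvent(*e) for e in events
        )
        by_channel: dict[str, list[PressEvent]] = {}
        for e in parsed:
            by_channel.setdefault(e.channel, []).append(e)
        for channel, evs in by_channel.items():
            evs = sorted(evs, key=lambda e: e.onset_time)
            for a, b in zip(evs, evs[1:]):
                if a.onset_time + a.duration > b.onset_time:
                    raise ValueError(f"overlapping press events on channel {channel!r}")
        object.__setattr__(self, "events", parsed)

    def for_channel(self, channel: str) -> list[PressEvent]:
        return [e for e in self.events if e.channel == channel]

    @property
    def channels(self) -> set[str]:
        return {e.channel for e in self.events}


@dataclass(frozen=True)
class GaitSpec:
    """Lower-limb regime: at rest (standing) or walking at a given cadence."""

    regime: str = "standing"
    cadence: float = 1.5  # steps/s, walking only
    stance_fraction: float = 0.6  # fraction of the step cycle in ground contact

    def __post_init__(self) -> None:
        if self.regime not in ("standing", "walking"):
            raise ValueError("regime must be 'standing' or 'walking'")
        if self.regime == "walking" and self.cadence <= 0:
            raise ValueError("cadence must be > 0 when walking")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")


@dataclass
class ForceTrace:
    """Uniformly sampled multi-channel contact-force time series."""

    sampling_rate: float
    channels: dict[str, np.ndarray]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channel sequences must have equal length")
        for name, v in self.channels.items():
            if np.any(v < 0):
                raise ValueError(f"channel {name!r} contains negative force values")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration(self) -> float:
        return float(self.n_samples / self.sampling_rate)

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in trace (has {list(self.channels)})"
            ) from None


def _raised_cosine(t: np.ndarray, onset: float, duration: float, amplitude: float) -> np.ndarray:
    """Smooth unimodal press bump: 0 at the edges, `amplitude` at the centre."""
    phase = (t - onset) / duration
    bump = np.zeros_like(t)
    inside = (phase >= 0.0) & (phase <= 1.0)
    bump[inside] = 0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * phase[inside]))
    return bump


def _gait_peaks(t: np.ndarray, gait: GaitSpec, amplitude: float) -> np.ndarray:
    """Half-sine stance loading repeated every step cycle."""
    period = 1.0 / gait.cadence
    stance = gait.stance_fraction * period
    phase = np.mod(t, period)
    y = np.zeros_like(t)
    in_stance = phase < stance
    y[in_stance] = amplitude * np.sin(np.pi * phase[in_stance] / stance)
    return y


def generate_trace(
    gait: GaitSpec,
    specs: Sequence[ChannelSpec],
    presses: PressSchedule | None = None,
    duration: float = 10.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
) -> ForceTrace:
    """Generate a deterministic multi-channel insole trace.

    Walking produces periodic stance peaks on every channel at the stated
    cadence (large on heel/forefoot, small on the toes); standing leaves
    channels near baseline.  Each scheduled press adds a raised-cosine bump
    of the channel's press amplitude.  Zero-mean Gaussian noise of the
    channel's sd is added and the total is clipped at zero (forces cannot
    be negative).  The same seed and parameters give a bitwise-identical
    trace.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    presses = presses or PressSchedule()
    regions = {s.region for s in specs}
    unknown = presses.channels - regions
    if unknown:
        raise ValueError(f"press schedule references channels not in specs: {sorted(unknown)}")

    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    rng = np.random.default_rng(seed)

    channels: dict[str, np.ndarray] = {}
    for spec in specs:
        y = np.full(n, spec.baseline_force, dtype=float)
        if gait.regime == "walking":
            y += _gait_peaks(t, gait, spec.gait_peak_amplitude)
        for event in presses.for_channel(spec.region):
            y += _raised_cosine(t, event.onset_time, event.duration, spec.press_peak_amplitude)
        if spec.noise_sd > 0:
            y += rng.normal(0.0, spec.noise_sd, size=n)
        channels[spec.region] = np.clip(y, 0.0, None)
    return ForceTrace(sampling_rate=sampling_rate, channels=channels)


def write_trace(trace: ForceTrace, path: str | Path) -> None:
    """Write a trace as delimited text: header ``time_s,<ch>,...`` then rows."""
    frame = pd.DataFrame({"time_s": trace.times(), **trace.channels})
    frame.to_csv(path, index=False, float_format="%.10g")


def read_trace(path: str | Path) -> ForceTrace:
    """Read a delimited-text trace; the sampling rate is recovered from time_s."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"empty trace file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise TraceFormatError(f"malformed trace file {path}: {exc}") from exc
    if "time_s" not in frame.columns:
        raise TraceFormatError(f"trace file {path} lacks a 'time_s' column")
    if frame.isna().any().any():
        raise TraceFormatError(f"trace file {path} has ragged or non-numeric rows")
    times = frame["time_s"].to_numpy(dtype=float)
    if len(times) < 2:
        raise TraceFormatError("trace must contain at least two samples")
    dt = np.median(np.diff(times))
    if dt <= 0:
        raise TraceFormatError("time_s column is not strictly increasing")
    channels = {c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "time_s"}
    if not channels:
        raise TraceFormatError("trace file has no force channels")
    return ForceTrace(sampling_rate=float(1.0 / dt), channels=channels, start_time=float(times[0]))
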