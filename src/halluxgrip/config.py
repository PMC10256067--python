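"""YAML pipeline configuration and the end-to-end trace runner."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .controller import DistanceLevelMap, LogEvent, run_closed_loop
from .filters import FilterParams
from .posture import DEFAULT_T_A, PostureModel, fit_polynomial, load_reference_dataset
from .press_detect import (
    DEFAULT_MARGIN_FACTOR,
    DEFAULT_SCAN_TIME_B,
    calibrate_threshold,
)
from .simulate import DEFAULT_SAMPLING_RATE, ForceTrace, read_trace

__all__ = ["ConfigError", "PipelineConfig", "load_config", "save_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised for unknown keys, missing fields or out-of-range values."""


# Two scan windows of press-free signal: long enough to capture the filter
# warm-up transient and representative noise extremes in the threshold.
DEFAULT_CALIBRATION_S = 2 * DEFAULT_SCAN_TIME_B


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end decode-and-control loop needs.

    calibration_s is the length of the press-free preamble at the start of
    a trace used to calibrate the press threshold.
    """

    sampling_rate: float = DEFAULT_SAMPLING_RATE
    filter: FilterParams = field(default_factory=FilterParams)
    scan_time_b: float = DEFAULT_SCAN_TIME_B
    margin_factor: float = DEFAULT_MARGIN_FACTOR
    level_map: DistanceLevelMap = field(default_factory=DistanceLevelMap)
    t_A: float = DEFAULT_T_A
    seed: int = 0
    calibration_s: float = DEFAULT_CALIBRATION_S

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.scan_time_b <= 0:
            raise ConfigError("scan_time_b must be > 0")
        if self.margin_factor < 1:
            raise ConfigError("margin_factor must be >= 1")
        if self.t_A <= 0:
            raise ConfigError("t_A must be > 0")
        if self.calibration_s <= 0:
            raise ConfigError("calibration_s must be > 0")


def _to_dict(config: PipelineConfig) -> dict:
    return {
        "sampling_rate": config.sampling_rate,
        "filter": asdict(config.filter),
        "scan_time_b": config.scan_time_b,
        "margin_factor": config.margin_factor,
        "level_map": {int(k): float(v) for k, v in config.level_map.levels.items()},
        "t_A": config.t_A,
        "seed": config.seed,
        "calibration_s": config.calibration_s,
    }


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    known = {
        "sampling_rate", "filter", "scan_time_b", "margin_factor",
        "level_map", "t_A", "seed", "calibration_s",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "filter" in raw:
        fdict = raw["filter"]
        if not isinstance(fdict, dict):
            raise ConfigError("filter section must be a mapping")
        valid_filter = {f for f in FilterParams.__dataclass_fields__}
        bad = set(fdict) - valid_filter
        if bad:
            raise ConfigError(f"unknown filter keys: {sorted(bad)}")
        try:
            kwargs["filter"] = FilterParams(**fdict)
        except ValueError as exc:
            raise ConfigError(f"filter: {exc}") from exc
    if "level_map" in raw:
        try:
            kwargs["level_map"] = DistanceLevelMap(
                {int(k): float(v) for k, v in raw["level_map"].items()}
            )
        except (TypeError, ValueError, AttributeError) as exc:
            raise ConfigError(f"level_map: {exc}") from exc
    for key in ("sampling_rate", "scan_time_b", "margin_factor", "t_A", "seed", "calibration_s"):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        return PipelineConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def run_pipeline(
    config: PipelineConfig,
    trace: str | Path | ForceTrace,
    model: PostureModel | None = None,
) -> tuple[list[LogEvent], dict]:
    """Decode a whole trace and drive the simulated hand.

    Calibrates the press threshold on the filtered first ``calibration_s``
    seconds of the hallux channel (assumed press-free), then streams scan
    windows through the press counter and posture FSM.  Returns the event
    log plus a summary with per-window press counts, the commands issued
    and the final hand state.
    """
    if not isinstance(trace, ForceTrace):
        trace = read_trace(trace)
    if model is None:
        model = fit_polynomial(load_reference_dataset(config.t_A), 4)

    from .filters import filter_trace

    try:
        filtered = filter_trace(trace, "hallux", config.filter)
    except KeyError as exc:
        raise ConfigError(f"stage filter: {exc}") from exc
    n_cal = max(2, int(round(config.calibration_s * trace.sampling_rate)))
    calib = calibrate_threshold(filtered[:n_cal], config.margin_factor, "standing",
                                source_window=(0.0, config.calibration_s))
    events = run_closed_loop(
        trace, calib, model,
        level_map=config.level_map,
        scan_time_b=config.scan_time_b,
        filter_params=config.filter,
        t_A=config.t_A,
    )
    press_events = sum(e.S for e in events)
    summary = {
        "threshold_t": calib.threshold_t,
        "n_windows": len(list(range(0, trace.n_samples,
                                    max(2, int(round(config.scan_time_b * trace.sampling_rate)))))),
        "press_events": press_events,
        "open_commands": sum(1 for e in events if e.command.action == "open"),
        "close_commands": sum(1 for e in events if e.command.action == "close"),
        "final_openness_mm": events[-1].state.openness if events else 0.0,
    }
    return events, summary
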