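"""Recursive-average + scalar Kalman smoothing of contact-force channels.

The raw insole signal carries sensor circuit noise and toe-jitter
artefacts.  Smoothing is done in two stages: a causal moving average over
the last N samples (N defaulting to 50, inside the 40-60 range that works
well at 100 Hz), followed by a scalar Kalman filter that models the force
level as a slowly varying state observed with noise.  The cascade trades a
small group delay for a strong variance reduction, which is acceptable
here because the user opens the hand ahead of the grasp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import ForceTrace

__all__ = ["FilterParams", "KalmanState", "recursive_average", "kalman_step", "filter_trace"]


@dataclass(frozen=True)
class FilterParams:
    """Moving-average window plus scalar Kalman tuning.

    The state model is x_k = F x_{k-1} + B u_{k-1} + w, z_k = H x_k + v,
    with process-noise variance Q and measurement-noise variance R.  The
    defaults (F=1, B=0, H=1) are a random-walk force level with no control
    input.  x0 defaults to the first averaged sample when filtering a
    stream (None here).
    """

    window_length_N: int = 50
    F: float = 1.0
    B: float = 0.0
    H: float = 1.0
    Q: float = 1e-2
    R: float = 1.0
    x0: float | None = None
    P0: float = 1.0

    def __post_init__(self) -> None:
        if self.window_length_N < 1:
            raise ValueError("window_length_N must be >= 1")
        if self.Q < 0:
            raise ValueError("Q must be >= 0")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.P0 < 0:
            raise ValueError("P0 must be >= 0")


@dataclass(frozen=True)
class KalmanState:
    """Posterior state/covariance plus the prior from the last predict step."""

    x_est: float
    P: float
    x_pred: float = 0.0
    P_pred: float = 0.0


def recursive_average(samples: Sequence[float] | np.ndarray, window_length_N: int) -> np.ndarray:
    """Causal moving average: element k is the mean of the last min(k+1, N) samples.

    The warm-up (k < N-1) averages the available prefix rather than padding
    with fabricated pre-stream data, so the output has the input's length.
    """
    if window_length_N < 1:
        raise ValueError("window_length_N must be >= 1")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    n = window_length_N
    c = np.cumsum(x)
    out = np.empty_like(x)
    head = min(n, x.size)
    out[:head] = c[:head] / np.arange(1, head + 1)
    if x.size > n:
        out[n:] = (c[n:] - c[:-n]) / n
    return out


def kalman_step(
    state: KalmanState,
    z_k: float,
    u_prev: float = 0.0,
    params: FilterParams = FilterParams(),
) -> KalmanState:
    """One scalar predict/update cycle.

    Predict: x- = F x + B u,  P- = F² P + Q.
    Update:  K = P- H / (H² P- + R),  x' = x- + K (z - H x-),  P' = (1 - K H) P-.
    """
    x_pred = params.F * state.x_est + params.B * u_prev
    P_pred = params.F**2 * state.P + params.Q
    K = P_pred * params.H / (params.H**2 * P_pred + params.R)
    x_est = x_pred + K * (z_k - params.H * x_pred)
    P = (1.0 - K * params.H) * P_pred
    return KalmanState(x_est=x_est, P=P, x_pred=x_pred, P_pred=P_pred)


def _kalman_sweep(z: np.ndarray, params: FilterParams) -> np.ndarray:
    x0 = params.x0 if params.x0 is not None else float(z[0])
    state = KalmanState(x_est=x0, P=params.P0)
    out = np.empty_like(z)
    # scalar recursion unrolled for speed; mirrors kalman_step exactly
    F, B, H, Q, R = params.F, params.B, params.H, params.Q, params.R
    x, P = state.x_est, state.P
    for k in range(z.size):
        x_pred = F * x
        P_pred = F * F * P + Q
        K = P_pred * H / (H * H * P_pred + R)
        x = x_pred + K * (z[k] - H * x_pred)
        P = (1.0 - K * H) * P_pred
        out[k] = x
    return out


def filter_trace(trace: ForceTrace, channel: str, params: FilterParams = FilterParams()) -> np.ndarray:
    """Recursive average then a Kalman sweep (u ≡ 0) over one trace channel."""
    raw = trace.channel(channel)
    if raw.size == 0:
        raise ValueError("channel is empty")
    averaged = recursive_average(raw, params.window_length_N)
    return _kalman_sweep(averaged, params)
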