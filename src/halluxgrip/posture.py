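"""Interfinger-distance <-> opening-time calibration of the assistive hand.

The single-degree-of-freedom hand has no position encoder: the only way to
reach a target interfinger distance l is to drive the open line for the
right duration.  Calibration measures, for a set of distances l_i, the
drive time t_i needed to open from fully closed, expressed as the time
ratio d_i = t_i / t_A where t_A is the full-open time.  A degree-M
polynomial d(l) is then fit by least squares; the drive time for any
target distance follows as t_open = d(l) x t_A.

The polynomial is fit on a centered-and-scaled abscissa for conditioning.
The fitted function, its SSE and its R^2 are invariant to that affine
substitution (a degree-M polynomial space is closed under it), so the fit
diagnostics are well-defined regardless of the scaling convention.

The reference calibration table (23 distance/time-ratio pairs for a hand
with a 100 mm full-open span) ships with the package; a quartic (M=4)
captures it with SSE ~0.0018 and R^2 ~0.9987, and increasing M further
buys almost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PostureDataset",
    "PostureModel",
    "load_reference_dataset",
    "time_ratio",
    "design_matrix",
    "fit_polynomial",
    "select_order",
    "predict_ratio",
    "opening_time",
]

FULL_OPEN_MM = 100.0
DEFAULT_T_A = 2.0  # s; nominal full-open time of the hand
DEFAULT_ELBOW_TOL = 0.20  # relative SSE improvement below this is "not worth it"


@dataclass(frozen=True)
class PostureDataset:
    """Calibration pairs (distance mm, time ratio) plus the full-open time."""

    sizes_mm: np.ndarray
    time_ratios: np.ndarray
    t_A: float = DEFAULT_T_A

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes_mm, dtype=float)
        ratios = np.asarray(self.time_ratios, dtype=float)
        if sizes.shape != ratios.shape or sizes.ndim != 1:
            raise ValueError("sizes_mm and time_ratios must be equal-length 1-D arrays")
        if sizes.size < 2:
            raise ValueError("need at least two calibration pairs")
        if np.any(sizes < 0) or np.any(sizes > FULL_OPEN_MM):
            raise ValueError(f"distances must lie in [0, {FULL_OPEN_MM}] mm")
        if np.any(ratios <= 0) or np.any(ratios > 1):
            raise ValueError("time ratios must lie in (0, 1]")
        if self.t_A <= 0:
            raise ValueError("t_A must be > 0")
        object.__setattr__(self, "sizes_mm", sizes)
        object.__setattr__(self, "time_ratios", ratios)

    @property
    def n(self) -> int:
        return int(self.sizes_mm.size)


@dataclass(frozen=True)
class PostureModel:
    """Fitted polynomial d(l) = b + sum_i w_i lambda^i, lambda = (l-shift)/scale."""

    order_M: int
    intercept_b: float
    coeffs_w: tuple[float, ...]
    abscissa_shift: float
    abscissa_scale: float
    SSE: float
    R2: float

    def __post_init__(self) -> None:
        if self.order_M < 1:
            raise ValueError("order_M must be >= 1")
        if len(self.coeffs_w) != self.order_M:
            raise ValueError("need exactly order_M coefficients")
        if self.SSE < 0:
            raise ValueError("SSE must be >= 0")
        if self.abscissa_scale <= 0:
            raise ValueError("abscissa_scale must be > 0")


def load_reference_dataset(t_A: float = DEFAULT_T_A) -> PostureDataset:
    """The packaged 23-pair opening-time calibration table."""
    with resources.files("halluxgrip.data").joinpath("table5.csv").open() as fh:
        frame = pd.read_csv(fh)
    return PostureDataset(
        sizes_mm=frame["size_mm"].to_numpy(),
        time_ratios=frame["time_ratio"].to_numpy(),
        t_A=t_A,
    )


def time_ratio(t_i: float, t_A: float) -> float:
    """d_i = t_i / t_A."""
    if t_A <= 0:
        raise ValueError("t_A must be > 0")
    return t_i / t_A


def design_matrix(l: np.ndarray, order_M: int, shift: float, scale: float) -> np.ndarray:
    """Vandermonde matrix [1, lambda, ..., lambda^M] on the transformed abscissa."""
    lam = (np.asarray(l, dtype=float) - shift) / scale
    return np.vander(lam, order_M + 1, increasing=True)


def fit_polynomial(data: PostureDataset, order_M: int) -> PostureModel:
    """Least-squares polynomial of degree M through the calibration pairs.

    Solves min_w ||L w - d||^2 for the (M+1)-vector (b, w_1..w_M); SSE is
    the residual sum of squares and R^2 = 1 - SSE / SS_tot.
    """
    if order_M < 1:
        raise ValueError("order_M must be >= 1")
    if order_M >= data.n:
        raise ValueError(f"order_M={order_M} must be < number of pairs ({data.n})")
    shift = float(np.mean(data.sizes_mm))
    scale = float(np.std(data.sizes_mm))
    if scale == 0.0:
        raise ValueError("calibration distances are all identical (rank-deficient fit)")
    L = design_matrix(data.sizes_mm, order_M, shift, scale)
    if np.linalg.matrix_rank(L) < order_M + 1:
        raise ValueError("rank-deficient design matrix")
    w, *_ = np.linalg.lstsq(L, data.time_ratios, rcond=None)
    resid = data.time_ratios - L @ w
    sse = float(resid @ resid)
    ss_tot = float(np.sum((data.time_ratios - np.mean(data.time_ratios)) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    return PostureModel(
        order_M=order_M,
        intercept_b=float(w[0]),
        coeffs_w=tuple(float(c) for c in w[1:]),
        abscissa_shift=shift,
        abscissa_scale=scale,
        SSE=sse,
        R2=min(max(r2, 0.0), 1.0),
    )


def select_order(
    data: PostureDataset,
    max_M: int = 6,
    rel_tol: float = DEFAULT_ELBOW_TOL,
) -> tuple[int, pd.DataFrame]:
    """Pick the polynomial degree by an SSE elbow rule.

    Fits M = 1..max_M and stops at the last degree before the relative SSE
    improvement first drops below ``rel_tol``: past the elbow, extra terms
    buy almost no fit at real computational and overfitting cost.  On the
    reference table this picks M = 4.  Returns (chosen_M, diagnostics) with
    one (M, SSE, R2) row per fitted degree.
    """
    if max_M < 1:
        raise ValueError("max_M must be >= 1")
    if max_M >= data.n:
        raise ValueError("max_M must be < number of pairs")
    rows = []
    for M in range(1, max_M + 1):
        model = fit_polynomial(data, M)
        rows.append({"M": M, "SSE": model.SSE, "R2": model.R2})
    diagnostics = pd.DataFrame(rows)

    chosen = max_M
    sse = diagnostics["SSE"].to_numpy()
    for M in range(2, max_M + 1):
        prev, cur = sse[M - 2], sse[M - 1]
        # an essentially-zero SSE cannot be meaningfully improved upon
        improvement = 0.0 if prev < 1e-12 else (prev - cur) / prev
        if improvement < rel_tol:
            chosen = M - 1
            break
    return chosen, diagnostics


def predict_ratio(model: PostureModel, l: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted time ratio at distance l (mm), clamped to [0, 1]."""
    arr = np.asarray(l, dtype=float)
    if np.any(arr < 0) or np.any(arr > FULL_OPEN_MM):
        raise ValueError(f"distance must lie in [0, {FULL_OPEN_MM}] mm")
    lam = (arr - model.abscissa_shift) / model.abscissa_scale
    coeffs = np.array((model.intercept_b,) + model.coeffs_w)
    d = np.polynomial.polynomial.polyval(lam, coeffs)
    d = np.clip(d, 0.0, 1.0)
    return float(d) if np.isscalar(l) or arr.ndim == 0 else d


def opening_time(model: PostureModel, l: float, t_A: float) -> float:
    """Drive time from fully closed to distance l: t_open = d(l) x t_A."""
    if t_A <= 0:
        raise ValueError("t_A must be > 0")
    return float(predict_ratio(model, l)) * t_A
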