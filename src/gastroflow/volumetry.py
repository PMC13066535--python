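"""Gastric content volume series and emptying kinetics.

Gastric content volume (GCV, mL) is measured by voxel counting in
segmented static volumes; its postprandial decline is summarized by

* the emptying rate, the (negated) least-squares slope dV/dt over an
  explicit fit window, in mL/min;
* a kinetic fit of either order with its half-life:
  first order  V(t) = c0 * exp(-k t),  t_1/2 = ln(2)/k,
  zero order   V(t) = c0 - k t,        t_1/2 = c0/(2 k).

First-order parameters come from ordinary least squares on ln V
(exact for noiseless data); fit windows are explicit arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .exceptions import InsufficientDataError

__all__ = [
    "VolumeSeries",
    "EmptyingFit",
    "emptying_rate",
    "half_life_first_order",
    "half_life_zero_order",
    "fit_emptying",
]

ModelOrder = Literal["first", "zero"]


@dataclass
class VolumeSeries:
    """Gastric content volumes (mL) at strictly increasing times (min)."""

    times: np.ndarray
    volumes: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.shape != self.volumes.shape or self.times.ndim != 1:
            raise ValueError("times and volumes must be 1-D and equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class EmptyingFit:
    """Fitted emptying kinetics over an explicit time window.

    ``k`` is per-min (first order) or mL/min (zero order); ``c0`` is the
    fitted initial volume in mL; ``half_life_min`` satisfies the closed
    form of the fitted order.  ``rmse_ml`` is the root-mean-square
    residual on the volume scale within the window.
    """

    model_order: ModelOrder
    k: float
    c0: float
    half_life_min: float
    fit_window: tuple[float, float]
    rmse_ml: float
    n_points: int


def _window_mask(series: VolumeSeries, window: Optional[tuple[float, float]]) -> np.ndarray:
    if window is None:
        return np.ones(len(series), dtype=bool)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window ({t0}, {t1})")
    return (series.times >= t0) & (series.times <= t1)


def emptying_rate(
    series: VolumeSeries, window: Optional[tuple[float, float]] = None
) -> float:
    """Emptying rate dV/dt (mL/min) over a time window.

    The negated ordinary-least-squares slope of volume against time over
    the in-window points; positive while the stomach empties.
    """
    mask = _window_mask(series, window)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"emptying rate needs >= 2 points in window, got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(series.times[mask], series.volumes[mask], 1)
    return -float(slope)


def half_life_first_order(k: float) -> float:
    """Half-life (min) of first-order emptying, ln(2)/k; k in per-min."""
    if k <= 0:
        raise ValueError(f"first-order rate constant must be > 0, got {k}")
    return math.log(2.0) / k


def half_life_zero_order(c0: float, k: float) -> float:
    """Half-life (min) of zero-order emptying, c0/(2k); k in mL/min."""
    if k <= 0:
        raise ValueError(f"zero-order rate constant must be > 0, got {k}")
    if c0 < 0:
        raise ValueError(f"initial volume must be >= 0, got {c0}")
    return c0 / (2.0 * k)


def fit_emptying(
    series: VolumeSeries,
    model_order: ModelOrder,
    window: Optional[tuple[float, float]] = None,
) -> EmptyingFit:
    """Fit emptying kinetics of the given order over a time window.

    Zero order: OLS of V on t; c0 is the intercept, k the negated slope.
    First order: OLS of ln V on t; c0 = exp(intercept), k = negated slope.
    The half-life is filled from the closed form of the fitted order, with
    the fitted (not observed) c0 for zero order.

    Raises if fewer than 3 points fall inside the window, or — for first
    order — if any in-window volume is non-positive (truncate the window
    to the region of measurable content instead).
    """
    if model_order not in ("first", "zero"):
        raise ValueError(f"unknown model order {model_order!r}")
    mask = _window_mask(series, window)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(f"kinetic fit needs >= 3 points in window, got {n}")
    t = series.times[mask]
    v = series.volumes[mask]
    win = (float(t[0]), float(t[-1])) if window is None else (float(window[0]), float(window[1]))

    if model_order == "zero":
        slope, intercept = np.polyfit(t, v, 1)
        k = -float(slope)
        c0 = float(intercept)
        half_life = half_life_zero_order(max(c0, 0.0), k) if k > 0 else math.inf
        predicted = intercept + slope * t
    else:
        if np.any(v <= 0):
            raise ValueError(
                "first-order fit requires strictly positive volumes in the window; "
                "truncate the window to exclude emptied timepoints"
            )
        slope, intercept = np.polyfit(t, np.log(v), 1)
        k = -float(slope)
        c0 = float(np.exp(intercept))
        half_life = half_life_first_order(k) if k > 0 else math.inf
        predicted = np.exp(intercept + slope * t)

    rmse = float(np.sqrt(np.mean((v - predicted) ** 2)))
    return EmptyingFit(
        model_order=model_order,
        k=k,
        c0=c0,
        half_life_min=half_life,
        fit_window=win,
        rmse_ml=rmse,
        n_points=n,
    )
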