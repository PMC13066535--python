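"""Intensity-threshold segmentation of bright-lumen images.

The manganese-labeled gastric content is T1-bright on a dark background,
so a deterministic relative-intensity threshold with connected-component
filtering is sufficient to delineate the lumen on phantom and bright-lumen
data.  Externally produced masks (e.g. expert-corrected) can be supplied
to the downstream analysis instead.

Connectivity is 4-neighborhood in 2D and 6-neighborhood in 3D.  Each
frame of a dynamic series is segmented independently; there is no
temporal regularization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .motility import AreaTimeSeries

__all__ = [
    "SegmentationParams",
    "segment_frame",
    "segment_stack",
    "mask_area",
    "mask_volume",
    "stack_to_area_series",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of threshold segmentation.

    threshold : fraction of the per-frame maximum intensity; relative so
        the result is invariant to global intensity scaling.
    min_component_area : mm^2; connected components smaller than this are
        discarded as speckle.
    keep_largest_only : keep only the largest connected component.
    """

    threshold: float = 0.5
    min_component_area: float = 0.0
    keep_largest_only: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")


def _connectivity_structure(ndim: int) -> np.ndarray:
    # rank-1 structuring element: 4-connectivity in 2D, 6 in 3D
    return ndimage.generate_binary_structure(ndim, 1)


def segment_frame(
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    pixel_spacing: float | Sequence[float] = 1.0,
) -> np.ndarray:
    """Segment one 2-D frame into a binary lumen mask.

    Pixels at or above ``threshold * max(image)`` form candidate
    components; components below ``min_component_area`` are removed, and
    optionally only the largest survives.  A constant (or non-positive)
    frame yields an empty mask rather than an error.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    peak = image.max()
    if peak <= image.min() or peak <= 0:
        return np.zeros(image.shape, dtype=np.uint8)
    mask = image >= params.threshold * peak

    structure = _connectivity_structure(image.ndim)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros(image.shape, dtype=np.uint8)

    pixel_area = float(np.prod(np.broadcast_to(np.asarray(pixel_spacing, dtype=float), (2,))))
    counts = np.bincount(labels.ravel())[1:]  # component sizes, label 1..n
    keep = counts * pixel_area >= params.min_component_area
    if params.keep_largest_only and np.any(keep):
        largest = np.argmax(np.where(keep, counts, -1))
        keep = np.zeros_like(keep)
        keep[largest] = True
    keep_labels = np.flatnonzero(keep) + 1
    return np.isin(labels, keep_labels).astype(np.uint8)


def segment_stack(
    images: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    pixel_spacing: float | Sequence[float] = 1.0,
) -> np.ndarray:
    """Segment a 2D+t stack (spatial axes first, time last) frame by frame."""
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError(f"expected a (ny, nx, nt) stack, got shape {images.shape}")
    out = np.empty(images.shape, dtype=np.uint8)
    for t in range(images.shape[-1]):
        out[..., t] = segment_frame(images[..., t], params, pixel_spacing)
    return out


def mask_area(mask: np.ndarray, pixel_spacing: float | Sequence[float]) -> float:
    """Foreground area of a 2-D binary mask in mm^2 (count x pixel area)."""
    mask = np.asarray(mask)
    _check_binary(mask)
    spacing = np.broadcast_to(np.asarray(pixel_spacing, dtype=float), (2,))
    return float(np.count_nonzero(mask) * spacing.prod())


def mask_volume(mask: np.ndarray, voxel_spacing: Sequence[float]) -> float:
    """Foreground volume of a 3-D binary mask in mL.

    Voxel counting: count x (product of spacings in mm) / 1000.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"volume requires 3 spatial axes, got {mask.ndim}")
    _check_binary(mask)
    spacing = np.asarray(voxel_spacing, dtype=float)
    if spacing.shape != (3,):
        raise ValueError("voxel_spacing must have 3 entries (mm)")
    return float(np.count_nonzero(mask) * spacing.prod() / 1000.0)


def stack_to_area_series(
    mask_stack: np.ndarray,
    pixel_spacing: float | Sequence[float],
    frame_rate: float,
    slice_index: int = 0,
    timepoint_id: str = "",
) -> AreaTimeSeries:
    """Convert a (ny, nx, nt) binary mask stack to an area-time series."""
    mask_stack = np.asarray(mask_stack)
    if mask_stack.ndim != 3:
        raise ValueError(f"expected a (ny, nx, nt) stack, got shape {mask_stack.shape}")
    areas = [mask_area(mask_stack[..., t], pixel_spacing) for t in range(mask_stack.shape[-1])]
    return AreaTimeSeries(
        areas=np.asarray(areas),
        frame_rate=frame_rate,
        slice_index=slice_index,
        timepoint_id=timepoint_id,
    )


def _check_binary(mask: np.ndarray) -> None:
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary (values in {0, 1})")
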