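"""File formats of the analysis pipeline.

NRRD carries image and mask stacks with spacing metadata (read and
written through SimpleITK); CSV carries area-time and volume-time tables;
the analysis report is machine-readable JSON; overlay frames for visual
segmentation review are PNG.

Axis convention: spatial axes first, temporal axis last.  A 2D+t stack is
``(ny, nx, nt)`` with axis order ``"yxt"``; a static volume is
``(nz, ny, nx)`` with axis order ``"zyx"``.  Frame and slice indices are
0-based internally; user-facing tables are 1-based to match radiological
convention.  Areas are mm^2, volumes mL, signal time s, protocol time min.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

from .exceptions import MetadataError, MultiLabelError, ShapeMismatchError
from .motility import AreaTimeSeries
from .volumetry import VolumeSeries

logger = logging.getLogger(__name__)

_KEY_FRAME_INTERVAL = "gastroflow_frame_interval"
_KEY_AXIS_ORDER = "gastroflow_axis_order"

__all__ = [
    "MaskStack",
    "AnalysisReport",
    "read_mask_stack",
    "write_mask_stack",
    "read_image_stack",
    "write_image_stack",
    "write_area_csv",
    "read_area_csv",
    "write_volume_csv",
    "read_volume_csv",
    "export_overlay_frames",
]


@dataclass
class MaskStack:
    """Binary lattice with spacing metadata.

    ``data`` holds values in {0, 1}; ``spacing`` is mm per spatial axis in
    the order of ``axis_order``; ``frame_interval`` (s) is present iff the
    stack has a temporal axis (axis order ``"yxt"``).
    """

    data: np.ndarray
    spacing: tuple
    axis_order: str = "yxt"
    frame_interval: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(np.unique(self.data), (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)
        if self.axis_order not in ("yxt", "zyx"):
            raise ValueError(f"unsupported axis order {self.axis_order!r}")
        if self.data.ndim != 3:
            raise ValueError(f"expected 3 axes, got {self.data.ndim}")
        n_spatial = 2 if self.axis_order == "yxt" else 3
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != n_spatial or any(s <= 0 for s in self.spacing):
            raise ValueError(
                f"need {n_spatial} positive spacing values, got {self.spacing}"
            )
        if self.axis_order == "yxt":
            if self.frame_interval is None or self.frame_interval <= 0:
                raise ValueError("temporal stacks need a positive frame_interval")
        elif self.frame_interval is not None:
            raise ValueError("static volumes carry no frame_interval")

    @property
    def frame_rate(self) -> Optional[float]:
        return None if self.frame_interval is None else 1.0 / self.frame_interval


# ---------------------------------------------------------------------------
# NRRD stacks
# ---------------------------------------------------------------------------

def _header_declares_spacing(path: Path) -> bool:
    """Check the plain-text NRRD header for a spacing field.

    SimpleITK silently defaults missing spacing to 1.0, so presence of the
    ``space directions``/``spacings`` key is checked on the raw header
    (everything before the first blank line).
    """
    head = b""
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line or line in (b"\n", b"\r\n"):
                break
            head += line
            if len(head) > 65536:
                break
    text = head.decode("ascii", errors="replace").lower()
    return "space directions:" in text or "spacings:" in text


def _to_sitk(data: np.ndarray, spacing: Sequence[float], axis_order: str,
             frame_interval: Optional[float]) -> sitk.Image:
    if axis_order == "yxt":
        # (ny, nx, nt) -> sitk array layout (nt, ny, nx); axis spacings (x, y, t)
        img = sitk.GetImageFromArray(np.moveaxis(data, -1, 0))
        sy, sx = spacing
        img.SetSpacing((float(sx), float(sy), float(frame_interval)))
        img.SetMetaData(_KEY_FRAME_INTERVAL, repr(float(frame_interval)))
    else:
        img = sitk.GetImageFromArray(data)  # (nz, ny, nx)
        sz, sy, sx = spacing
        img.SetSpacing((float(sx), float(sy), float(sz)))
    img.SetMetaData(_KEY_AXIS_ORDER, axis_order)
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, str, Optional[float]]:
    axis_order = (
        img.GetMetaData(_KEY_AXIS_ORDER) if img.HasMetaDataKey(_KEY_AXIS_ORDER) else "zyx"
    )
    arr = sitk.GetArrayFromImage(img)
    sx, sy, slast = img.GetSpacing()
    if axis_order == "yxt":
        data = np.moveaxis(arr, 0, -1)
        frame_interval = (
            float(img.GetMetaData(_KEY_FRAME_INTERVAL))
            if img.HasMetaDataKey(_KEY_FRAME_INTERVAL)
            else float(slast)
        )
        return data, (float(sy), float(sx)), axis_order, frame_interval
    return arr, (float(slast), float(sy), float(sx)), axis_order, None


def write_mask_stack(stack: MaskStack, path: str | Path) -> Path:
    """Write a binary mask stack to NRRD with spacing metadata."""
    path = Path(path)
    sitk.WriteImage(
        _to_sitk(stack.data, stack.spacing, stack.axis_order, stack.frame_interval),
        str(path),
    )
    return path


def read_mask_stack(
    path: str | Path, spacing_override: Optional[Sequence[float]] = None
) -> MaskStack:
    """Read an NRRD mask stack, binarizing a single foreground label.

    Voxel values greater than zero become 1; a file with more than one
    distinct foreground class raises :class:`MultiLabelError` naming the
    classes.  Missing spacing metadata raises :class:`MetadataError`
    unless ``spacing_override`` (mm per spatial axis) is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if spacing_override is None and not _header_declares_spacing(path):
        raise MetadataError(
            f"{path}: NRRD header declares no spacing; pass spacing_override"
        )
    data, spacing, axis_order, frame_interval = _from_sitk(sitk.ReadImage(str(path)))
    foreground = np.unique(data[data > 0])
    if foreground.size > 1:
        raise MultiLabelError(foreground.tolist())
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    return MaskStack(
        data=(data > 0).astype(np.uint8),
        spacing=spacing,
        axis_order=axis_order,
        frame_interval=frame_interval,
    )


def write_image_stack(
    data: np.ndarray,
    spacing: Sequence[float],
    path: str | Path,
    axis_order: str = "yxt",
    frame_interval: Optional[float] = None,
) -> Path:
    """Write a grayscale image stack (float) to NRRD with spacing metadata."""
    path = Path(path)
    sitk.WriteImage(
        _to_sitk(np.asarray(data, dtype=np.float32), spacing, axis_order, frame_interval),
        str(path),
    )
    return path


def read_image_stack(path: str | Path) -> tuple[np.ndarray, tuple, str, Optional[float]]:
    """Read a grayscale NRRD stack; returns (data, spacing, axis_order, frame_interval)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _from_sitk(sitk.ReadImage(str(path)))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_AREA_COLUMNS = ["timepoint_id", "slice_index", "frame_index", "time_s", "area_mm2"]


def write_area_csv(series_list: Sequence[AreaTimeSeries], path: str | Path) -> Path:
    """Write per-slice area-time curves as a long-format CSV table.

    One row per frame per slice with 1-based ``slice_index`` (matching
    radiological slice numbering); areas and times are written with six
    decimal places and round-trip losslessly at that precision.  Slices
    may have different lengths; an empty series list is an error.
    """
    if len(series_list) == 0:
        raise ValueError("refusing to write an empty area table")
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "timepoint_id": s.timepoint_id,
                    "slice_index": s.slice_index + 1,
                    "frame_index": np.arange(len(s)),
                    "time_s": s.times,
                    "area_mm2": s.areas,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)[_AREA_COLUMNS]
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6f")
    return path


def read_area_csv(path: str | Path) -> list[AreaTimeSeries]:
    """Read an area CSV back into per-slice series (ordered by slice)."""
    table = pd.read_csv(path)
    missing = set(_AREA_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"area table lacks columns {sorted(missing)}")
    out = []
    for (tp, slice_1based), group in table.groupby(
        ["timepoint_id", "slice_index"], sort=True, dropna=False
    ):
        group = group.sort_values("frame_index")
        times = group["time_s"].to_numpy()
        if times.size < 2:
            raise ValueError(f"slice {slice_1based}: need >= 2 frames to infer frame rate")
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-6):
            raise ValueError(f"slice {slice_1based}: non-uniform sampling in table")
        out.append(
            AreaTimeSeries(
                areas=group["area_mm2"].to_numpy(),
                frame_rate=1.0 / float(np.mean(dt)),
                slice_index=int(slice_1based) - 1,
                timepoint_id="" if pd.isna(tp) else str(tp),
            )
        )
    return out


def write_volume_csv(series: VolumeSeries, path: str | Path) -> Path:
    """Write a gastric-content-volume series as CSV (time_min, volume_ml)."""
    path = Path(path)
    pd.DataFrame(
        {"label": series.label, "time_min": series.times, "volume_ml": series.volumes}
    ).to_csv(path, index=False, float_format="%.6f")
    return path


def read_volume_csv(path: str | Path) -> VolumeSeries:
    table = pd.read_csv(path)
    missing = {"time_min", "volume_ml"} - set(table.columns)
    if missing:
        raise ValueError(f"volume table lacks columns {sorted(missing)}")
    label = str(table["label"].iloc[0]) if "label" in table.columns and len(table) else ""
    return VolumeSeries(
        times=table["time_min"].to_numpy(),
        volumes=table["volume_ml"].to_numpy(),
        label=label,
    )


# ---------------------------------------------------------------------------
# overlay frames
# ---------------------------------------------------------------------------

def export_overlay_frames(
    images: np.ndarray,
    masks: np.ndarray,
    out_dir: str | Path,
    prefix: str = "frame",
    stride: int = 1,
) -> list[Path]:
    """Export per-frame PNGs with the mask boundary drawn on the image.

    ``images`` and ``masks`` are ``(ny, nx, nt)`` stacks of identical
    shape; the boundary is the set of foreground pixels with a 4-neighbor
    outside the mask, drawn in red over the intensity-normalized frame.
    ``stride`` subsamples frames (every ``stride``-th frame is written).
    """
    images = np.asarray(images)
    masks = np.asarray(masks)
    if images.shape != masks.shape:
        raise ShapeMismatchError(images.shape, masks.shape)
    if images.ndim != 3:
        raise ValueError(f"expected (ny, nx, nt) stacks, got shape {images.shape}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lo, hi = float(images.min()), float(images.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    structure = ndimage.generate_binary_structure(2, 1)

    paths = []
    for t in range(0, images.shape[-1], stride):
        gray = ((images[..., t] - lo) * scale).astype(np.uint8)
        rgb = np.stack([gray, gray, gray], axis=-1)
        mask = masks[..., t].astype(bool)
        if mask.any():
            boundary = mask & ~ndimage.binary_erosion(mask, structure=structure)
            rgb[boundary] = (255, 0, 0)
        path = out_dir / f"{prefix}_{t:05d}.png"
        iio.imwrite(path, rgb)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# analysis report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Machine-readable summary of one pipeline run.

    Every metric is keyed by the series identifier it came from; the
    report embeds the configuration hash and software version so a run is
    reproducible from its persisted configuration.  Serialization is
    canonical (sorted keys) and idempotent.
    """

    version: str
    config_hash: str
    inputs: list = field(default_factory=list)
    motility: dict = field(default_factory=dict)
    volumetry: dict = field(default_factory=dict)
    dropouts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "inputs": list(self.inputs),
            "motility": self.motility,
            "volumetry": self.volumetry,
            "dropouts": list(self.dropouts),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        payload = json.loads(text)
        return cls(
            version=payload["version"],
            config_hash=payload["config_hash"],
            inputs=payload.get("inputs", []),
            motility=payload.get("motility", {}),
            volumetry=payload.get("volumetry", {}),
            dropouts=payload.get("dropouts", []),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisReport":
        return cls.from_json(Path(path).read_text())
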