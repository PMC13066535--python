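"""End-to-end orchestration: simulate -> segment -> motility/volumetry -> report.

A run is fully described by a :class:`RunConfig`; identical configuration
and seed reproduce identical outputs.  Stage outputs are written in the
formats the next stage reads, so externally corrected masks can replace a
stage's output and the downstream stages rerun unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .exceptions import DegenerateReferenceError, InsufficientDataError
from .imaging_io import (
    AnalysisReport,
    MaskStack,
    export_overlay_frames,
    write_area_csv,
    write_image_stack,
    write_mask_stack,
    write_volume_csv,
)
from .motility import FrequencyBand, SliceGeometry, analyze_timepoint
from .phantom import (
    EmptyingSpec,
    PhantomSpec,
    generate_dynamic_phantom,
    generate_emptying_series,
)
from .segmentation import SegmentationParams, segment_stack, stack_to_area_series
from .volumetry import fit_emptying

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

#: exit status of a run that completed with dropouts/partial results
EXIT_PARTIAL = 2


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    emptying: EmptyingSpec = field(default_factory=EmptyingSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    band: FrequencyBand = field(default_factory=FrequencyBand)
    dominance_threshold: float = 2.0
    top_fraction: float = 0.10
    fit_window: Optional[tuple[float, float]] = None
    grid_shape: tuple[int, int] = (140, 140)
    overlay_stride: int = 50
    out_dir: str = "gastroflow_run"
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed is not None:
            # one seed governs every stochastic stage
            self.phantom = dataclasses.replace(self.phantom, seed=int(self.seed))
            self.emptying = dataclasses.replace(self.emptying, seed=int(self.seed))

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["emptying"]["sample_times"] = list(self.emptying.sample_times)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "phantom" in payload:
            ph = dict(payload["phantom"])
            if "geometry" in ph:
                ph["geometry"] = SliceGeometry(**ph["geometry"])
            payload["phantom"] = PhantomSpec(**ph)
        if "emptying" in payload:
            em = dict(payload["emptying"])
            if "sample_times" in em:
                em["sample_times"] = tuple(em["sample_times"])
            payload["emptying"] = EmptyingSpec(**em)
        if "segmentation" in payload:
            payload["segmentation"] = SegmentationParams(**payload["segmentation"])
        if "band" in payload:
            payload["band"] = FrequencyBand(**payload["band"])
        for key in ("fit_window", "grid_shape"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @property
    def config_hash(self) -> str:
        # hash only the analysis-relevant fields: the same science written
        # to a different directory is the same run
        payload = self.to_dict()
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        canonical = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _frequency_entry(result) -> dict:
    return {
        "peak_frequency_cpm": round(result.peak_frequency_cpm, 6),
        "dominance_factor": round(result.dominance_factor, 6),
        "valid": result.valid,
    }


def _occlusion_entry(result) -> dict:
    return {
        "reference_area_mm2": round(result.reference_area, 6),
        "mean_occlusion_pct": round(result.mean_occlusion_pct, 6),
        "max_occlusion_pct": round(result.max_occlusion_pct, 6),
    }


def run_pipeline(config: RunConfig) -> tuple[AnalysisReport, int]:
    """Execute a full phantom run; returns (report, exit_status).

    Exit status 0 marks a complete run, ``EXIT_PARTIAL`` (2) a run where
    one or more slices were dropped (no foreground found) but the
    remaining analysis succeeded.  Per-slice decisions are logged, never
    silently discarded.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = config.phantom.geometry
    run_id = config.config_hash

    logger.info("run %s: generating dynamic phantom", run_id)
    dynamic = generate_dynamic_phantom(config.phantom, grid_shape=config.grid_shape)

    inputs = []
    for i, (image, mask) in enumerate(zip(dynamic.images, dynamic.masks)):
        img_path = out / f"slice{i + 1}_image.nrrd"
        write_image_stack(
            image, (geom.pixel_spacing, geom.pixel_spacing), img_path,
            axis_order="yxt", frame_interval=geom.frame_interval,
        )
        write_mask_stack(
            MaskStack(mask, (geom.pixel_spacing, geom.pixel_spacing),
                      "yxt", geom.frame_interval),
            out / f"slice{i + 1}_truth_mask.nrrd",
        )
        inputs.append(str(img_path))

    logger.info("run %s: segmenting %d slices", run_id, len(dynamic.images))
    series_list = []
    dropouts = []
    for i, image in enumerate(dynamic.images):
        masks = segment_stack(image, config.segmentation, geom.pixel_spacing)
        write_mask_stack(
            MaskStack(masks, (geom.pixel_spacing, geom.pixel_spacing),
                      "yxt", geom.frame_interval),
            out / f"slice{i + 1}_seg_mask.nrrd",
        )
        series = stack_to_area_series(
            masks, geom.pixel_spacing, geom.frame_rate,
            slice_index=i, timepoint_id=run_id,
        )
        if np.all(series.areas == 0):
            logger.warning("run %s: slice %d has no foreground; dropout", run_id, i + 1)
            dropouts.append({"slice_index": i + 1, "reason": "no foreground found"})
            continue
        series_list.append(series)

    if series_list:
        write_area_csv(series_list, out / "areas.csv")

    motility_section: dict = {}
    if series_list:
        try:
            report_tp = analyze_timepoint(
                series_list, geom, config.band,
                config.dominance_threshold, config.top_fraction,
                timepoint_id=run_id,
            )
            motility_section = {
                "slices": {
                    str(s.slice_index + 1): {
                        **_frequency_entry(f), **_occlusion_entry(o),
                        "series_id": f"{run_id}/slice{s.slice_index + 1}",
                    }
                    for s, f, o in zip(
                        series_list, report_tp.frequency, report_tp.occlusion
                    )
                },
                "n_valid_slices": report_tp.n_valid_slices,
                "mean_frequency_cpm": report_tp.mean_frequency_cpm,
                "propagation_distance_mm": report_tp.propagation_distance_mm,
                "apparent_speed_mm_s": report_tp.apparent_speed_mm_s,
                "crosscorr_speed_mm_s": (
                    report_tp.crosscorr.speed_mm_s if report_tp.crosscorr else None
                ),
            }
        except (InsufficientDataError, DegenerateReferenceError) as exc:
            logger.warning("run %s: motility analysis skipped: %s", run_id, exc)
            dropouts.append({"stage": "motility", "reason": str(exc)})
    else:
        dropouts.append({"stage": "motility", "reason": "all slices dropped out"})

    logger.info("run %s: emptying series and kinetic fit", run_id)
    volume_series = generate_emptying_series(config.emptying)
    write_volume_csv(volume_series, out / "volumes.csv")
    volumetry_section: dict = {"series_id": f"{run_id}/volumes"}
    try:
        fit = fit_emptying(volume_series, config.emptying.model_order, config.fit_window)
        volumetry_section.update(
            model_order=fit.model_order,
            k=round(fit.k, 9),
            c0_ml=round(fit.c0, 6),
            half_life_min=round(fit.half_life_min, 6),
            rmse_ml=round(fit.rmse_ml, 6),
            n_points=fit.n_points,
        )
    except (InsufficientDataError, ValueError) as exc:
        logger.warning("run %s: kinetic fit failed: %s", run_id, exc)
        dropouts.append({"stage": "volumetry", "reason": str(exc)})

    if dynamic.images:
        export_overlay_frames(
            dynamic.images[0],
            segment_stack(dynamic.images[0], config.segmentation, geom.pixel_spacing),
            out / "overlays",
            prefix="slice1",
            stride=config.overlay_stride,
        )

    report = AnalysisReport(
        version=__version__,
        config_hash=run_id,
        inputs=inputs,
        motility=motility_section,
        volumetry=volumetry_section,
        dropouts=dropouts,
    )
    report.save(out / "report.json")
    config.to_yaml(out / "config.yaml")
    status = EXIT_PARTIAL if dropouts else 0
    return report, status
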