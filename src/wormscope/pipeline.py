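"""End-to-end plate processing: image in, worm count + boxes + masks out.

Two entry routes share one report format:

* :func:`run_classical` — the contour-based chain (dish mask, optional
  tiling, classical segmentation, cross-tile merge), useful as annotation
  generator and desk-scale baseline.
* :func:`run_external` — consumes a detection file produced by an external
  learned detector and applies the inference filter chain.

Reports carry provenance (pixel-buffer hash, config hash, package version)
so identical inputs and configuration provably yield identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image, ImageDraw

from . import __version__
from .classicseg import SegmentationParams, segment_plate
from .detproc import DetFilterConfig, Detection, filter_chain, read_detections
from .dishmask import DishGeometry
from .evalmetrics import (
    Metrics,
    PRCurve,
    average_precision,
    iou_sweep,
    match_detections,
    precision_recall_f1,
)
from .instances import InstanceMask
from .synthgen import read_fixture
from .tiler import extract_tile, merge_tile_detections, plan_tiles, to_global

logger = logging.getLogger("wormscope")

__all__ = [
    "PipelineConfig",
    "PlateReport",
    "run_classical",
    "run_external",
    "run_evaluation",
    "render_overlay",
]


@dataclass
class TilingOptions:
    enabled: bool = False
    tile_w: int = 820
    tile_h: int = 821
    overlap: float = 0.25
    merge_iou: float = 0.3


@dataclass
class EvaluationOptions:
    iou_min: float = 0.5
    mode: str = "mask"
    sweep_thresholds: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class PipelineConfig:
    """Single structured configuration governing every stage."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tiling: TilingOptions = field(default_factory=TilingOptions)
    detection_filter: DetFilterConfig = field(default_factory=DetFilterConfig)
    evaluation: EvaluationOptions = field(default_factory=EvaluationOptions)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a nested dict (e.g. parsed JSON); unknown keys rejected."""
        return _dataclass_from_dict(cls, data, "config")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _dataclass_from_dict(cls, data: dict, where: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        default = names[key].default_factory() if names[key].default_factory is not dataclasses.MISSING else None
        if isinstance(value, dict) and default is not None and dataclasses.is_dataclass(default):
            kwargs[key] = _dataclass_from_dict(type(default), value, f"{where}.{key}")
        else:
            kwargs[key] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


@dataclass
class PlateReport:
    """Result of one plate: surviving detections and their provenance."""

    worm_count: int
    detections: list[Detection]
    metrics: Metrics | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self, frame_shape: tuple[int, int] | None = None) -> dict:
        dets = []
        for d in self.detections:
            entry = {
                "id": d.id,
                "bbox": [float(v) for v in d.bbox],
                "score": float(d.score),
                "label": d.label,
            }
            if d.mask is not None:
                entry["mask_area"] = d.mask.area
            dets.append(entry)
        out = {
            "worm_count": self.worm_count,
            "detections": dets,
            "provenance": self.provenance,
        }
        if self.metrics is not None:
            out["metrics"] = dataclasses.asdict(self.metrics)
        return out


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        return np.asarray(iio.imread(image))
    return np.asarray(image)


def _provenance(image: np.ndarray, config: PipelineConfig) -> dict:
    # hash the decoded pixel buffer, not the file, so recompression is harmless
    pixel_hash = hashlib.sha256(np.ascontiguousarray(image).tobytes()).hexdigest()
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"image_sha256": pixel_hash, "config_sha256": cfg_hash, "version": __version__}


def run_classical(image, config: PipelineConfig | None = None) -> PlateReport:
    """Classical route: dish mask -> (tile ->) segment -> merge -> report.

    Each surviving worm gets a sequential ID; classical masks carry score
    1.0 (the chain has no confidence notion).
    """
    config = config or PipelineConfig()
    img = _load_image(image)
    seg = config.segmentation

    if config.tiling.enabled:
        t = config.tiling
        grid = plan_tiles(img.shape[1], img.shape[0], t.tile_w, t.tile_h, t.overlap)
        # the dish is located once on the full image, not per tile
        from .dishmask import DishNotFoundError, apply_dish_mask, detect_dish, full_image_geometry

        work = img
        if seg.apply_dish:
            try:
                geom = detect_dish(img, seg.luminance_jump, margin_fraction=seg.dish_margin)
            except DishNotFoundError:
                if seg.on_dish_error == "raise":
                    raise
                geom = full_image_geometry(img)
            work = apply_dish_mask(img, geom)
        tile_params = dataclasses.replace(seg, apply_dish=False)
        all_dets: list[Detection] = []
        next_id = 0
        H, W = img.shape[:2]
        for offset in grid.offsets:
            tile = extract_tile(work, offset, grid.tile_w, grid.tile_h)
            for m in segment_plate(tile, tile_params):
                # fragments cut by a tile border are covered whole by a
                # neighboring tile (the overlap exceeds one worm span), so
                # drop them unless the border is also an image border
                x0, y0, x1, y1 = m.bbox
                if (
                    (x0 == 0 and offset[0] > 0)
                    or (y0 == 0 and offset[1] > 0)
                    or (x1 == grid.tile_w and offset[0] + grid.tile_w < W)
                    or (y1 == grid.tile_h and offset[1] + grid.tile_h < H)
                ):
                    continue
                det = Detection(bbox=tuple(float(v) for v in m.bbox), score=1.0, mask=m, id=next_id)
                next_id += 1
                all_dets.append(to_global(det, offset))
        logger.info("tiled segmentation: %d raw detections over %d tiles", len(all_dets), len(grid))
        dets = merge_tile_detections(all_dets, config.tiling.merge_iou)
    else:
        masks = segment_plate(img, seg)
        dets = [
            Detection(bbox=tuple(float(v) for v in m.bbox), score=1.0, mask=m, id=i)
            for i, m in enumerate(masks)
        ]
    for i, d in enumerate(dets):
        d.id = i
    logger.info("classical route: %d worms", len(dets))
    return PlateReport(
        worm_count=len(dets), detections=dets, provenance=_provenance(img, config)
    )


def run_external(image, detections_path, config: PipelineConfig | None = None) -> PlateReport:
    """External-detector route: read detection file, filter, merge, report."""
    config = config or PipelineConfig()
    img = _load_image(image)
    raw = read_detections(detections_path)
    dets, stages = filter_chain(raw, config.detection_filter, return_stage_counts=True)
    for name, count in stages:
        logger.info("filter stage %-16s -> %d detections", name, count)
    if any(d.tile_offset is not None for d in raw):
        dets = [to_global(d, d.tile_offset) if d.tile_offset else d for d in dets]
        dets = merge_tile_detections(dets, config.tiling.merge_iou)
        logger.info("cross-tile merge -> %d detections", len(dets))
    for i, d in enumerate(dets):
        d.id = i
    return PlateReport(
        worm_count=len(dets), detections=dets, provenance=_provenance(img, config)
    )


def run_evaluation(
    report: PlateReport,
    truth,
    config: PipelineConfig | None = None,
):
    """Score a report against ground truth; returns (Metrics, PRCurve, sweep).

    ``truth`` is a list of :class:`InstanceMask` or a fixture manifest path.
    """
    config = config or PipelineConfig()
    ev = config.evaluation
    if isinstance(truth, (str, Path)):
        _, gts, _ = read_fixture(truth)
    else:
        gts = list(truth)
    m = match_detections(report.detections, gts, iou_min=ev.iou_min, mode=ev.mode)
    metrics = precision_recall_f1(m)
    curve = average_precision(report.detections, gts, iou_min=ev.iou_min, mode=ev.mode)
    sweep = iou_sweep(report.detections, gts, ev.sweep_thresholds, mode=ev.mode)
    report.metrics = metrics
    return metrics, curve, sweep


_MASK_COLOR = np.array([70, 90, 220], dtype=float)  # blue-ish fill
_BOX_COLOR = (220, 40, 40)
_TEXT_COLOR = (240, 220, 40)


def render_overlay(image, report: PlateReport, out_path: str | Path | None = None) -> np.ndarray:
    """Draw masks (blue), boxes (red) and IDs (yellow) onto a copy of the image.

    Purely cosmetic: never alters the report. Deterministic. Returns the
    annotated RGB array; also writes it to ``out_path`` when given.
    """
    img = _load_image(image)
    if img.ndim == 2:
        rgb = np.stack([img] * 3, axis=-1).astype(float)
    else:
        rgb = img[..., :3].astype(float)

    for d in report.detections:
        if d.mask is None:
            continue
        x0, y0, x1, y1 = d.mask.bbox
        region = rgb[y0:y1, x0:x1]
        sel = d.mask.pixels
        region[sel] = 0.5 * region[sel] + 0.5 * _MASK_COLOR

    pil = Image.fromarray(np.clip(np.round(rgb), 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(pil)
    for d in report.detections:
        x0, y0, x1, y1 = d.bbox
        draw.rectangle([x0, y0, x1 - 1, y1 - 1], outline=_BOX_COLOR, width=1)
        draw.text((x0 + 2, max(y0 - 12, 0)), str(d.id), fill=_TEXT_COLOR)
    out = np.asarray(pil)
    if out_path is not None:
        iio.imwrite(Path(out_path), out)
    return out
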