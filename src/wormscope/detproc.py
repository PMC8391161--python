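"""Detection-side post-processing: NMS, confidence/size filtering, config I/O.

The detection network itself (a Mask R-CNN) runs elsewhere, at GPU scale;
this module consumes its outputs — bounding boxes, confidence scores, class
labels and optional instance masks — and applies the inference-time filter
chain: background removal, a confidence floor, per-class non-maximum
suppression, a top-k cap and a minimum-size filter. It also emits the full
training/inference configuration (anchors, ratios, learning schedule) as a
JSON file for users attaching an external detector framework.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .classicseg import SizeFilterParams
from .instances import InstanceMask

__all__ = [
    "Detection",
    "DetFilterConfig",
    "MrcnnConfigSpec",
    "DetectionParseError",
    "nms",
    "filter_chain",
    "emit_mrcnn_config",
    "read_mrcnn_config",
    "read_detections",
    "write_detections",
]


@dataclass
class Detection:
    """One candidate worm: half-open box, score, label, optional mask."""

    bbox: tuple[float, float, float, float]
    score: float
    label: str = "worm"
    mask: InstanceMask | None = None
    id: int = 0
    tile_offset: tuple[int, int] | None = None

    def __post_init__(self):
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"bbox must satisfy x0 < x1 and y0 < y1, got {self.bbox}")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")

    @property
    def box_area(self) -> float:
        x0, y0, x1, y1 = self.bbox
        return (x1 - x0) * (y1 - y0)

    @property
    def short_edge(self) -> float:
        x0, y0, x1, y1 = self.bbox
        return min(x1 - x0, y1 - y0)


@dataclass
class DetFilterConfig:
    """Inference-time filter chain parameters.

    The confidence floor of 0.92 and the per-class NMS threshold of 0.3 are
    the operating point of the whole-plate worm detector; proposal-stage
    values are carried for completeness.
    """

    score_min: float = 0.92
    per_class_nms_iou: float = 0.3
    max_detections: int = 100
    size_filter: SizeFilterParams = field(default_factory=SizeFilterParams)
    proposal_nms_iou: float = 0.5
    max_proposals: int = 1000

    def __post_init__(self):
        for name in ("score_min", "per_class_nms_iou", "proposal_nms_iou"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_detections <= 0 or self.max_proposals <= 0:
            raise ValueError("max_detections and max_proposals must be positive")


@dataclass
class MrcnnConfigSpec:
    """Mask R-CNN training/inference recipe, serialized verbatim.

    ``rpn_anchor_scale`` is an opaque passthrough knob of the upstream
    framework; it is stored but not interpreted here.
    """

    anchor_scales: tuple[int, ...] = (32, 64, 86, 128, 172)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    rpn_nms_threshold: float = 0.7
    rpn_anchor_scale: int = 18
    train_rois_per_image: int = 256
    roi_positive_ratio: str = "1:3"
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 100
    warp_size: tuple[int, int] = (768, 768)
    backbone: str = "ResNet-101"
    detection_max: int = 100
    detection_min_confidence: float = 0.0


def _box_iou(a: tuple, b: tuple) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def _score_order(detections: list[Detection]) -> list[Detection]:
    # ties broken by lower id for determinism
    return sorted(detections, key=lambda d: (-d.score, d.id))


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression on box IoU.

    Repeatedly keeps the highest-scoring remaining detection and suppresses
    every other detection whose box IoU with it is >= ``iou_threshold``.
    Output is sorted by descending score (ties: lower id first). Idempotent.
    """
    remaining = _score_order(detections)
    kept: list[Detection] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [d for d in remaining if _box_iou(best.bbox, d.bbox) < iou_threshold]
    return kept


def filter_chain(
    detections: list[Detection],
    cfg: DetFilterConfig | None = None,
    return_stage_counts: bool = False,
):
    """Apply the inference filter chain in order.

    1. drop background-labeled detections,
    2. drop detections scoring below ``score_min``,
    3. per-class greedy NMS at ``per_class_nms_iou``,
    4. keep the ``max_detections`` top scores,
    5. minimum-size filter on boxes (small-area AND short-edge test).

    With ``return_stage_counts=True`` also returns ``[(stage, count), ...]``
    including the input count, so the attrition through the chain is
    auditable.
    """
    cfg = cfg or DetFilterConfig()
    stages: list[tuple[str, int]] = [("input", len(detections))]

    dets = [d for d in detections if d.label != "background"]
    stages.append(("drop_background", len(dets)))

    dets = [d for d in dets if d.score >= cfg.score_min]
    stages.append(("score_min", len(dets)))

    by_class: dict[str, list[Detection]] = {}
    for d in dets:
        by_class.setdefault(d.label, []).append(d)
    dets = [d for group in by_class.values() for d in nms(group, cfg.per_class_nms_iou)]
    dets = _score_order(dets)
    stages.append(("per_class_nms", len(dets)))

    dets = dets[: cfg.max_detections]
    stages.append(("top_k", len(dets)))

    sf = cfg.size_filter
    dets = [d for d in dets if not sf.is_too_small(d.box_area, d.short_edge)]
    stages.append(("size_filter", len(dets)))

    if return_stage_counts:
        return dets, stages
    return dets


# ---------------------------------------------------------------------------
# configuration and detection file I/O


def emit_mrcnn_config(spec: MrcnnConfigSpec, path: str | Path) -> Path:
    """Serialize the detector recipe to JSON; round-trips losslessly."""
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(spec), indent=1))
    return path


def read_mrcnn_config(path: str | Path) -> MrcnnConfigSpec:
    data = json.loads(Path(path).read_text())
    spec = MrcnnConfigSpec(**data)
    # JSON turns tuples into lists; normalize back
    spec.anchor_scales = tuple(spec.anchor_scales)
    spec.anchor_ratios = tuple(spec.anchor_ratios)
    spec.warp_size = tuple(spec.warp_size)
    return spec


class DetectionParseError(ValueError):
    """A detection file entry violates the schema."""


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detection JSON file.

    Schema::

        {"detections": [{"id": int, "bbox": [x0, y0, x1, y1], "score": float,
                         "label": str, "mask_file": str?, "tile_offset": [x, y]?},
                        ...]}

    ``mask_file`` paths are resolved relative to the JSON file. Malformed
    entries raise :class:`DetectionParseError` naming the entry index and
    field.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    if "detections" not in data:
        raise DetectionParseError("missing top-level 'detections' key")
    out: list[Detection] = []
    for i, entry in enumerate(data["detections"]):
        for key in ("bbox", "score"):
            if key not in entry:
                raise DetectionParseError(f"entry {i}: missing field '{key}'")
        bbox = entry["bbox"]
        if len(bbox) != 4:
            raise DetectionParseError(f"entry {i}: bbox must have 4 values")
        x0, y0, x1, y1 = (float(v) for v in bbox)
        if not (x0 < x1 and y0 < y1):
            raise DetectionParseError(f"entry {i}: field 'bbox' must satisfy x0 < x1 and y0 < y1")
        score = float(entry["score"])
        if not (0.0 <= score <= 1.0):
            raise DetectionParseError(f"entry {i}: field 'score' must lie in [0, 1]")
        mask = None
        if entry.get("mask_file"):
            arr = iio.imread(path.parent / entry["mask_file"])
            if arr.ndim == 3:
                arr = arr[..., 0]
            mask = InstanceMask(arr > 0)
        tile_offset = entry.get("tile_offset")
        out.append(
            Detection(
                bbox=(x0, y0, x1, y1),
                score=score,
                label=entry.get("label", "worm"),
                mask=mask,
                id=int(entry.get("id", i)),
                tile_offset=tuple(tile_offset) if tile_offset is not None else None,
            )
        )
    return out


def write_detections(
    detections: list[Detection], path: str | Path, frame_shape: tuple[int, int] | None = None
) -> Path:
    """Inverse of :func:`read_detections`; masks (if any) written as PNGs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, d in enumerate(detections):
        entry = {
            "id": d.id,
            "bbox": [float(v) for v in d.bbox],
            "score": float(d.score),
            "label": d.label,
        }
        if d.tile_offset is not None:
            entry["tile_offset"] = list(d.tile_offset)
        if d.mask is not None:
            if frame_shape is None:
                raise ValueError("frame_shape required to serialize masks")
            name = f"{path.stem}_mask_{i:03d}.png"
            iio.imwrite(path.parent / name, d.mask.to_full(frame_shape).astype(np.uint8) * 255)
            entry["mask_file"] = name
        entries.append(entry)
    path.write_text(json.dumps({"detections": entries}, indent=1))
    return path
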