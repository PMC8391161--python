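"""Sliding-window tiling of whole-plate images and cross-tile merging.

Full-resolution plates (3280 x 2464 px) are processed in 820 x 821 px
chunks with 25% overlap so every worm appears whole in at least one chunk.
The stride is floor(tile * (1 - overlap)); the last tile in each axis is
clamped to the image border rather than padded, so all tiles keep the exact
nominal size and every pixel is covered. Detections made in tile
coordinates are translated back to the full-image frame and de-duplicated
with a greedy overlap rule (same philosophy as per-class NMS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detproc import Detection, _score_order
from .evalmetrics import box_iou, mask_iou

__all__ = ["TileGrid", "plan_tiles", "extract_tile", "to_global", "merge_tile_detections"]


@dataclass
class TileGrid:
    """Tile layout over one image: nominal size, overlap, top-left offsets."""

    tile_w: int
    tile_h: int
    overlap: float
    image_w: int
    image_h: int
    offsets: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.offsets)


def _axis_offsets(dim: int, tile: int, overlap: float) -> list[int]:
    stride = max(int(np.floor(tile * (1.0 - overlap))), 1)
    offsets: list[int] = []
    x = 0
    while True:
        if x + tile >= dim:
            last = dim - tile
            if not offsets or offsets[-1] != last:
                offsets.append(last)
            break
        offsets.append(x)
        x += stride
    return offsets


def plan_tiles(
    image_w: int,
    image_h: int,
    tile_w: int = 820,
    tile_h: int = 821,
    overlap: float = 0.25,
) -> TileGrid:
    """Plan a fully covering, fully in-bounds tile grid.

    Offsets advance by floor(tile * (1 - overlap)); the final offset in each
    axis is clamped to ``image_dim - tile_dim`` (overlapping its neighbor by
    more than the nominal fraction). The nominal geometry (820 x 821 at 25%
    on a 3280 x 2464 plate) yields a 5 x 4 grid of 20 tiles.
    """
    if tile_w > image_w or tile_h > image_h:
        raise ValueError("tile must not exceed the image in either dimension")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    xs = _axis_offsets(image_w, tile_w, overlap)
    ys = _axis_offsets(image_h, tile_h, overlap)
    offsets = [(x, y) for y in ys for x in xs]
    return TileGrid(tile_w, tile_h, overlap, image_w, image_h, offsets)


def extract_tile(
    image: np.ndarray, offset: tuple[int, int], tile_w: int, tile_h: int
) -> np.ndarray:
    """Copy out the sub-image at ``offset`` = (x0, y0)."""
    x0, y0 = offset
    H, W = image.shape[:2]
    if x0 < 0 or y0 < 0 or x0 + tile_w > W or y0 + tile_h > H:
        raise ValueError(f"tile at {offset} exceeds image bounds")
    return image[y0 : y0 + tile_h, x0 : x0 + tile_w].copy()


def to_global(detection: Detection, offset: tuple[int, int]) -> Detection:
    """Translate a tile-frame detection into full-image coordinates."""
    dx, dy = offset
    x0, y0, x1, y1 = detection.bbox
    return Detection(
        bbox=(x0 + dx, y0 + dy, x1 + dx, y1 + dy),
        score=detection.score,
        label=detection.label,
        mask=detection.mask.translate(dx, dy) if detection.mask is not None else None,
        id=detection.id,
        tile_offset=None,
    )


def merge_tile_detections(
    detections: list[Detection], iou_threshold: float = 0.3
) -> list[Detection]:
    """De-duplicate detections of the same worm seen in overlapping tiles.

    Greedy by descending score: a detection is dropped when its IoU with an
    already kept detection reaches ``iou_threshold``. Mask IoU is used when
    both detections carry masks, box IoU otherwise. Output sorted by
    descending score.
    """
    kept: list[Detection] = []
    for d in _score_order(detections):
        duplicate = False
        for k in kept:
            if d.mask is not None and k.mask is not None:
                iou = mask_iou(d.mask, k.mask)
            else:
                iou = box_iou(d.bbox, k.bbox)
            if iou >= iou_threshold:
                duplicate = True
                break
        if not duplicate:
            kept.append(d)
    return kept
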