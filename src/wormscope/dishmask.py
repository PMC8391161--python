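"""Locate the Petri dish in a whole-plate image and blacken its outside.

The dish rim is contrast-rich and regularly triggers false worm detections,
so everything outside the (slightly shrunk) agar circle is zeroed before any
segmentation or detection runs. The circle is found from a single horizontal
scan line through the vertical image center: the leftmost and rightmost
strong luminance transitions on that line are taken as the horizontal
diameter endpoints of the dish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DishGeometry", "DishNotFoundError", "detect_dish", "apply_dish_mask"]

#: half-width of the windowed luminance difference used for edge detection
_EDGE_LAG = 3
#: moving-average width applied to the scan line before differencing
_SMOOTH = 5


class DishNotFoundError(RuntimeError):
    """No luminance transition found on the central scan line."""


@dataclass
class DishGeometry:
    """Circle bounding the usable agar region.

    ``margin_fraction`` shrinks the radius when masking, excluding the
    contrast-rich rim band just inside the detected dish edge.
    """

    center_x: float
    center_y: float
    radius: float
    margin_fraction: float = 0.05

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0 <= self.margin_fraction < 0.5):
            raise ValueError("margin_fraction must lie in [0, 0.5)")

    @property
    def effective_radius(self) -> float:
        return self.radius * (1.0 - self.margin_fraction)


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image.astype(float).mean(axis=2)
    return image.astype(float)


def detect_dish(
    image: np.ndarray,
    luminance_jump: float | None = None,
    margin_fraction: float = 0.05,
) -> DishGeometry:
    """Find the dish circle from the horizontal center scan line.

    The scan line is smoothed with a width-5 moving average; an edge is any
    position where the absolute luminance difference across a +-3 px window
    exceeds ``luminance_jump`` (default: 25% of the image's dynamic range).
    The centers of the first and last super-threshold runs are the left and
    right dish edges. If only one run is found (dish partly out of frame),
    the missing edge is clamped to the image border.

    Raises
    ------
    DishNotFoundError
        If no transition exceeds the threshold (e.g. a uniform image).
    """
    gray = _to_gray(image)
    if gray.size == 0:
        raise ValueError("image is empty")
    H, W = gray.shape
    row = gray[H // 2].astype(float)

    kernel = np.ones(_SMOOTH) / _SMOOTH
    smooth = np.convolve(row, kernel, mode="same")

    dyn = float(gray.max() - gray.min())
    if luminance_jump is None:
        luminance_jump = 0.25 * dyn
    if dyn == 0 or luminance_jump <= 0:
        raise DishNotFoundError("dish not found: image has no luminance variation")

    lag = _EDGE_LAG
    diff = np.abs(smooth[2 * lag :] - smooth[: -2 * lag])  # centered at i+lag
    hits = np.nonzero(diff > luminance_jump)[0] + lag
    if hits.size == 0:
        raise DishNotFoundError("dish not found: no luminance transition on scan line")

    # split hit positions into contiguous runs; edge = run center
    splits = np.nonzero(np.diff(hits) > 1)[0] + 1
    runs = np.split(hits, splits)
    left = float(np.mean(runs[0]))
    right = float(np.mean(runs[-1]))

    if len(runs) == 1:
        # single visible edge: the other side is off-image; clamp to border
        if left < W / 2:
            right = float(W - 1)
        else:
            right, left = left, 0.0
    radius = (right - left) / 2.0
    if radius <= 0:
        raise DishNotFoundError("dish not found: degenerate edge geometry")
    return DishGeometry(
        center_x=(left + right) / 2.0,
        center_y=H / 2.0,
        radius=radius,
        margin_fraction=margin_fraction,
    )


def full_image_geometry(image: np.ndarray, margin_fraction: float = 0.0) -> DishGeometry:
    """Fallback circle covering the whole image (circumscribed)."""
    H, W = image.shape[:2]
    return DishGeometry(
        center_x=W / 2.0,
        center_y=H / 2.0,
        radius=float(np.hypot(W, H)) / 2.0 + 1.0,
        margin_fraction=margin_fraction,
    )


def apply_dish_mask(image: np.ndarray, geom: DishGeometry) -> np.ndarray:
    """Zero every pixel farther than ``geom.effective_radius`` from the center.

    Interior pixels are bit-identical to the input; the operation is
    idempotent. Works on grayscale and RGB images alike.
    """
    H, W = image.shape[:2]
    yy, xx = np.mgrid[0:H, 0:W]
    outside = (xx - geom.center_x) ** 2 + (yy - geom.center_y) ** 2 > geom.effective_radius**2
    out = image.copy()
    out[outside] = 0
    return out
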