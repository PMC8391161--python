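"""Core pixel-level container: the instance mask of a single worm.

Masks are stored as a tight bounding-box crop plus an (x0, y0) offset into
the full image frame, so whole-plate images with many instances stay cheap.
Coordinates follow image convention: x = column, y = row; bounding boxes
are half-open ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["InstanceMask"]


class InstanceMask:
    """Binary pixel set of one object, cropped to its minimal bounding box.

    Parameters
    ----------
    pixels : array-like of bool
        2-D foreground map. It is re-cropped to the tight bounding box of
        its nonzero pixels on construction, so ``bbox`` is always minimal.
    x0, y0 : int
        Position of ``pixels[0, 0]`` in the full image frame.
    """

    __slots__ = ("pixels", "x0", "y0")

    def __init__(self, pixels, x0: int = 0, y0: int = 0):
        arr = np.asarray(pixels, dtype=bool)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        ys, xs = np.nonzero(arr)
        if ys.size == 0:
            raise ValueError("mask has no foreground pixels")
        y_min, y_max = int(ys.min()), int(ys.max())
        x_min, x_max = int(xs.min()), int(xs.max())
        self.pixels = np.ascontiguousarray(arr[y_min : y_max + 1, x_min : x_max + 1])
        self.x0 = int(x0) + x_min
        self.y0 = int(y0) + y_min

    # -- geometry -----------------------------------------------------------

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Minimal half-open bounding box ``(x0, y0, x1, y1)``."""
        h, w = self.pixels.shape
        return (self.x0, self.y0, self.x0 + w, self.y0 + h)

    @property
    def bbox_xywh(self) -> tuple[int, int, int, int]:
        x0, y0, x1, y1 = self.bbox
        return (x0, y0, x1 - x0, y1 - y0)

    @property
    def area(self) -> int:
        """Number of foreground pixels."""
        return int(np.count_nonzero(self.pixels))

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid in full-frame coordinates."""
        ys, xs = np.nonzero(self.pixels)
        return (self.x0 + float(xs.mean()), self.y0 + float(ys.mean()))

    def coords(self) -> np.ndarray:
        """(N, 2) array of (x, y) foreground pixel coordinates, full frame."""
        ys, xs = np.nonzero(self.pixels)
        return np.column_stack([xs + self.x0, ys + self.y0])

    # -- conversions --------------------------------------------------------

    @classmethod
    def from_full(cls, full: np.ndarray) -> "InstanceMask":
        """Build from a full-frame boolean image."""
        return cls(full)

    def to_full(self, shape: tuple[int, int]) -> np.ndarray:
        """Paint the mask into a full-frame boolean array of ``shape`` (H, W)."""
        out = np.zeros(shape, dtype=bool)
        h, w = self.pixels.shape
        if self.y0 < 0 or self.x0 < 0 or self.y0 + h > shape[0] or self.x0 + w > shape[1]:
            raise ValueError("mask does not fit inside the requested frame")
        out[self.y0 : self.y0 + h, self.x0 : self.x0 + w] = self.pixels
        return out

    def translate(self, dx: int, dy: int) -> "InstanceMask":
        """Return a copy shifted by (dx, dy) pixels."""
        return InstanceMask(self.pixels, self.x0 + dx, self.y0 + dy)

    # -- set operations -----------------------------------------------------

    def intersection_area(self, other: "InstanceMask") -> int:
        ax0, ay0, ax1, ay1 = self.bbox
        bx0, by0, bx1, by1 = other.bbox
        x0, y0 = max(ax0, bx0), max(ay0, by0)
        x1, y1 = min(ax1, bx1), min(ay1, by1)
        if x1 <= x0 or y1 <= y0:
            return 0
        a = self.pixels[y0 - ay0 : y1 - ay0, x0 - ax0 : x1 - ax0]
        b = other.pixels[y0 - by0 : y1 - by0, x0 - bx0 : x1 - bx0]
        return int(np.count_nonzero(a & b))

    def __eq__(self, other) -> bool:
        if not isinstance(other, InstanceMask):
            return NotImplemented
        return (
            self.x0 == other.x0
            and self.y0 == other.y0
            and self.pixels.shape == other.pixels.shape
            and bool(np.array_equal(self.pixels, other.pixels))
        )

    def __hash__(self):  # identity hash; masks are mutable arrays
        return id(self)

    def __repr__(self) -> str:
        return f"InstanceMask(bbox={self.bbox}, area={self.area})"
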