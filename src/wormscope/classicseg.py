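"""Classical worm segmentation: the semi-automatic mask-extraction chain.

A contour-based pipeline that turns a whole-plate brightfield image into
per-worm instance masks without any learned model. It is both the reference
annotation generator and a usable classical baseline detector:

    dish mask -> bilateral denoise -> grayscale -> Gaussian adaptive
    threshold -> morphological closing + opening -> connected components ->
    blob filter (shape descriptors) -> minimum-size filter -> worm area band

Worms appear darker than the agar, so thresholding keeps pixels below the
local Gaussian-weighted mean minus a constant. Round artifacts (trapped
air/gas bubbles in the agar) are separated from worms by their shape:
a blob is small (area <= 700 px²), fairly convex, non-degenerate in
circularity, and isotropic (inertia ratio >= 0.2) — adult worms are larger
and strongly elongated, so they fail the conjunction and are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing as _closing, disk, opening as _opening
from skimage.restoration import denoise_bilateral
from skimage.filters import threshold_local

from .dishmask import DishGeometry, DishNotFoundError, apply_dish_mask, detect_dish, full_image_geometry
from .instances import InstanceMask

__all__ = [
    "BlobFilterParams",
    "ShapeDescriptors",
    "SizeFilterParams",
    "WormAreaBand",
    "SegmentationParams",
    "bilateral_denoise",
    "to_grayscale",
    "adaptive_binarize",
    "morph_clean",
    "shape_descriptors",
    "filter_blobs",
    "size_filter",
    "extract_worm_masks",
    "segment_plate",
]


@dataclass
class BlobFilterParams:
    """Shape ranges describing removable round blobs (not worms)."""

    area_range: tuple[float, float] = (0.0, 700.0)
    convexity_range: tuple[float, float] = (0.3, 1.0)
    circularity_min: float = 0.2
    inertia_range: tuple[float, float] = (0.2, 1.0)

    def __post_init__(self):
        for name in ("area_range", "convexity_range", "inertia_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")
        for name in ("convexity_range", "inertia_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo and hi <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ShapeDescriptors:
    """Contour/moment descriptors of one connected component.

    circularity = 4*pi*area / perimeter²  (1 for an ideal disc)
    convexity   = area / convex-hull area
    inertia_ratio = minor/major principal second central moment
    """

    area: float
    perimeter: float
    convexity: float
    circularity: float
    inertia_ratio: float


@dataclass
class SizeFilterParams:
    """Minimum meaningful segment size, tested on bounding boxes.

    With ``combine='and'`` (default) a segment is removed only when its box
    area is below ``min_bbox_area`` AND its shorter box edge is below
    ``min_edge``; ``combine='or'`` removes on either condition.
    """

    min_bbox_area: float = 700.0
    min_edge: float = 24.0
    combine: str = "and"

    def __post_init__(self):
        if self.min_bbox_area < 0 or self.min_edge < 0:
            raise ValueError("size thresholds must be >= 0")
        if self.combine not in ("and", "or"):
            raise ValueError("combine must be 'and' or 'or'")

    def is_too_small(self, bbox_area: float, short_edge: float) -> bool:
        small_area = bbox_area < self.min_bbox_area
        small_edge = short_edge < self.min_edge
        return (small_area and small_edge) if self.combine == "and" else (small_area or small_edge)


@dataclass
class WormAreaBand:
    """Plausible adult-worm mask area range (px²)."""

    min_area: float = 250.0
    max_area: float = 5000.0

    def __post_init__(self):
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")

    def contains(self, area: float) -> bool:
        return self.min_area <= area <= self.max_area


# ---------------------------------------------------------------------------
# pixel-level stages


def bilateral_denoise(
    image: np.ndarray,
    diameter: int = 9,
    sigma_color: float = 10.0,
    sigma_space: float = 5.0,
) -> np.ndarray:
    """Edge-preserving denoise: spatial-and-range weighted neighborhood mean.

    ``sigma_color`` is in 8-bit gray levels; ``diameter`` is the square
    neighborhood width. Output has the input's dtype (rounded for uint8).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    img = np.asarray(image)
    float_in = np.issubdtype(img.dtype, np.floating)
    work = img.astype(float) if float_in else img.astype(float) / 255.0
    sigma_c = sigma_color if float_in else sigma_color / 255.0
    kwargs = dict(
        win_size=diameter, sigma_color=sigma_c, sigma_spatial=sigma_space, mode="reflect"
    )
    if work.ndim == 3:
        out = denoise_bilateral(work, channel_axis=-1, **kwargs)
    else:
        out = denoise_bilateral(work, **kwargs)
    if float_in:
        return out
    return np.clip(np.round(out * 255.0), 0, 255).astype(img.dtype)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB -> single channel via Rec.709 luma weighting; grayscale passes through."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    gray = rgb2gray(img[..., :3])  # returns float in [0, 1] for uint8 input
    if np.issubdtype(img.dtype, np.floating):
        return gray
    return np.clip(np.round(gray * 255.0), 0, 255).astype(img.dtype)


def adaptive_binarize(gray: np.ndarray, window: int = 71, offset_c: float = 4.0) -> np.ndarray:
    """Gaussian adaptive threshold keeping pixels darker than their locality.

    A pixel is foreground iff value < (Gaussian-weighted local mean over a
    ``window``-px neighborhood) - ``offset_c``: dark worms on bright agar
    become foreground, uniform regions become background.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("adaptive_binarize expects a single-channel image")
    thresh = threshold_local(gray.astype(float), block_size=window, method="gaussian", offset=offset_c)
    return gray < thresh


def morph_clean(binary: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Closing (fill holes in large objects) then opening (remove specks)."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd and >= 1")
    if kernel_size == 1:
        return np.asarray(binary, dtype=bool).copy()
    footprint = disk(kernel_size // 2)  # 3x3 cross for the default
    binary = np.asarray(binary, dtype=bool)
    return _opening(_closing(binary, footprint), footprint)


# ---------------------------------------------------------------------------
# component-level stages


def shape_descriptors(component: InstanceMask) -> ShapeDescriptors:
    """Compute area/perimeter/moment descriptors of one component.

    The perimeter is the Crofton estimate (accurate for smooth rasterized
    contours); circularity may slightly exceed 1 for tiny components due to
    discretization.
    """
    if component.area == 0:
        raise ValueError("component is empty")
    rp = regionprops(component.pixels.astype(np.uint8))[0]
    area = float(rp.area)
    perimeter = float(rp.perimeter_crofton)
    convexity = area / float(rp.area_convex)
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0
    lam1, lam2 = rp.inertia_tensor_eigvals  # lam1 >= lam2 >= 0
    inertia_ratio = float(lam2 / lam1) if lam1 > 0 else 1.0
    return ShapeDescriptors(
        area=area,
        perimeter=perimeter,
        convexity=convexity,
        circularity=circularity,
        inertia_ratio=inertia_ratio,
    )


def _is_blob(d: ShapeDescriptors, p: BlobFilterParams) -> bool:
    return (
        p.area_range[0] <= d.area <= p.area_range[1]
        and p.convexity_range[0] <= d.convexity <= p.convexity_range[1]
        and d.circularity > p.circularity_min
        and p.inertia_range[0] <= d.inertia_ratio <= p.inertia_range[1]
    )


def filter_blobs(
    components: list[InstanceMask], params: BlobFilterParams | None = None
) -> list[InstanceMask]:
    """Remove components whose descriptors fall inside ALL blob ranges.

    Elongated worms escape via their low inertia ratio (and usually area);
    round bubbles and droplets satisfy every range and are dropped.
    """
    params = params or BlobFilterParams()
    return [c for c in components if not _is_blob(shape_descriptors(c), params)]


def size_filter(
    masks: list[InstanceMask], params: SizeFilterParams | None = None
) -> list[InstanceMask]:
    """Drop segments too small to be meaningful, judged on bounding boxes."""
    params = params or SizeFilterParams()
    out = []
    for m in masks:
        x0, y0, x1, y1 = m.bbox
        if not params.is_too_small((x1 - x0) * (y1 - y0), min(x1 - x0, y1 - y0)):
            out.append(m)
    return out


def extract_worm_masks(
    binary: np.ndarray,
    band: WormAreaBand | None = None,
    blob_params: BlobFilterParams | None = None,
    size_params: SizeFilterParams | None = None,
    connectivity: int = 2,
) -> list[InstanceMask]:
    """Connected components of ``binary`` surviving all worm filters.

    8-connected labeling; each surviving component is one instance mask
    encoding a single worm (crossing worms merge — a known limitation).
    """
    band = band or WormAreaBand()
    labeled = cc_label(np.asarray(binary, dtype=bool), connectivity=connectivity)
    comps = [
        InstanceMask(rp.image, x0=rp.bbox[1], y0=rp.bbox[0])
        for rp in regionprops(labeled)
    ]
    comps = filter_blobs(comps, blob_params)
    comps = size_filter(comps, size_params)
    return [c for c in comps if band.contains(c.area)]


@dataclass
class SegmentationParams:
    """All knobs of the classical chain, with stage-skipping flags."""

    bilateral_diameter: int = 9
    bilateral_sigma_color: float = 10.0
    bilateral_sigma_space: float = 5.0
    window: int = 71
    offset_c: float = 4.0
    kernel_size: int = 3
    blob: BlobFilterParams = field(default_factory=BlobFilterParams)
    size: SizeFilterParams = field(default_factory=SizeFilterParams)
    band: WormAreaBand = field(default_factory=WormAreaBand)
    dish_margin: float = 0.05
    luminance_jump: float | None = None
    on_dish_error: str = "full"  # "full": fall back to whole-image circle; "raise"
    apply_dish: bool = True
    apply_bilateral: bool = True
    apply_morphology: bool = True
    apply_blob_filter: bool = True
    apply_size_filter: bool = True
    apply_band_filter: bool = True


def segment_plate(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    dish_geometry: DishGeometry | None = None,
) -> list[InstanceMask]:
    """Run the full classical chain on one plate image. Deterministic.

    ``dish_geometry`` overrides detection (e.g. when the caller already
    masked the plate); with ``params.on_dish_error == 'full'`` a failed dish
    detection degrades to a whole-image circle instead of raising.
    """
    p = params or SegmentationParams()
    img = np.asarray(image)

    if p.apply_dish:
        geom = dish_geometry
        if geom is None:
            try:
                geom = detect_dish(img, p.luminance_jump, margin_fraction=p.dish_margin)
            except DishNotFoundError:
                if p.on_dish_error == "raise":
                    raise
                geom = full_image_geometry(img)
        img = apply_dish_mask(img, geom)

    if p.apply_bilateral:
        img = bilateral_denoise(
            img, p.bilateral_diameter, p.bilateral_sigma_color, p.bilateral_sigma_space
        )
    gray = to_grayscale(img)
    binary = adaptive_binarize(gray, p.window, p.offset_c)
    if p.apply_morphology:
        binary = morph_clean(binary, p.kernel_size)

    # a circularity floor above 1 makes the blob test unsatisfiable (filter off)
    no_blob = BlobFilterParams(circularity_min=2.0)
    return extract_worm_masks(
        binary,
        band=p.band if p.apply_band_filter else WormAreaBand(0.0, float(np.inf)),
        blob_params=p.blob if p.apply_blob_filter else no_blob,
        size_params=p.size if p.apply_size_filter else SizeFilterParams(0.0, 0.0),
    )
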