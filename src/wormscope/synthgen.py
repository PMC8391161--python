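"""Synthetic whole-plate brightfield image generator with exact ground truth.

Emulates the appearance of an agar-filled Petri dish photographed in
transmitted light: a bright circular agar disc surrounded by a dark rim
annulus on a dark background, with thin dark curved nematodes, near-circular
dark blob artifacts (trapped air/gas bubbles in the agar) and additive
Gaussian sensor noise. Every worm comes with its exact per-instance binary
mask, so the downstream segmentation and evaluation stages can be verified
without any microscope.

Worm shape model: the body midline ("skeleton") is a unit-step random-heading
walk whose heading increment is Normal(0, turn_sigma); this produces the
smooth sinusoidal postures adult C. elegans adopt on agar. The body is the
union of discs centered on the skeleton, with the half-width tapering toward
head and tail. Worms are steered back toward the dish center whenever a step
would leave the usable agar region, so ground-truth masks always lie inside
the dish circle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import line as draw_line
from scipy.ndimage import binary_dilation

from .instances import InstanceMask

__all__ = [
    "SynthConfig",
    "WormInstance",
    "generate_dish_image",
    "render_worm",
    "write_fixture",
    "read_fixture",
]


@dataclass
class SynthConfig:
    """Parameters of one synthetic plate.

    Defaults emulate the full-resolution capture geometry (3280 x 2464 px,
    a dish nearly filling the short axis) with a realistic worm load of 25
    adults per plate. Tests and desk-scale runs shrink everything; the
    geometry scales freely.

    Gray levels are 8-bit. Worms and blobs are darker than the agar
    (brightfield transmitted-light convention).
    """

    image_width: int = 3280
    image_height: int = 2464
    dish_center: tuple[int, int] | None = None  # defaults to image center
    dish_radius: int | None = None  # defaults to min(w,h)/2 - rim_width - 2
    rim_width: int = 60
    n_worms: int = 25
    # adult-worm geometry: calibrated so rendered masks comfortably exceed the
    # 700 px² / 24 px minimum-size filters even for tightly curled postures
    worm_length_range: tuple[int, int] = (100, 160)
    worm_halfwidth: float = 4.5
    n_blobs: int = 8
    blob_radius_range: tuple[float, float] = (5.0, 12.0)
    noise_sigma: float = 3.0
    background_level: int = 200  # agar
    worm_level: int = 70
    blob_level: int = 90
    rim_level: int = 30
    outside_level: int = 5
    turn_sigma: float = 0.25  # radians per unit skeleton step
    allow_overlap: bool = True
    #: worms are confined within dish_radius * (1 - containment_margin), so a
    #: downstream dish mask with its default 5% rim shrink never clips them
    containment_margin: float = 0.08
    seed: int = 0

    def resolved_center(self) -> tuple[int, int]:
        if self.dish_center is not None:
            return (int(self.dish_center[0]), int(self.dish_center[1]))
        return (self.image_width // 2, self.image_height // 2)

    def resolved_radius(self) -> int:
        if self.dish_radius is not None:
            return int(self.dish_radius)
        return min(self.image_width, self.image_height) // 2 - self.rim_width - 2

    def validate(self) -> None:
        """Raise ValueError naming the offending field."""
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image_width/image_height must be positive")
        r = self.resolved_radius()
        if r <= 0:
            raise ValueError("dish_radius must be positive")
        if r + self.rim_width > min(self.image_width, self.image_height) / 2:
            raise ValueError(
                "dish_radius: dish_radius + rim_width must fit within "
                "min(image_width, image_height)/2"
            )
        if self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        lo, hi = self.worm_length_range
        if lo > hi or lo < 2:
            raise ValueError("worm_length_range must satisfy 2 <= min <= max")
        if self.worm_halfwidth < 0:
            raise ValueError("worm_halfwidth must be >= 0")
        blo, bhi = self.blob_radius_range
        if blo > bhi or blo < 0:
            raise ValueError("blob_radius_range must satisfy 0 <= min <= max")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class WormInstance:
    """One generated worm: midline, per-point half-width, rendered mask."""

    skeleton: np.ndarray  # (N, 2) float (x, y)
    halfwidth_profile: np.ndarray  # (N,) float px
    mask: InstanceMask


def _halfwidth_profile(n: int, halfwidth: float) -> np.ndarray:
    """Body half-width along the midline, tapering toward both ends."""
    t = np.linspace(0.0, 1.0, n)
    taper = np.clip(np.minimum(t, 1.0 - t) / 0.15, 0.3, 1.0)
    return halfwidth * taper


def render_worm(
    skeleton: np.ndarray,
    halfwidth_profile: np.ndarray,
    image_shape: tuple[int, int],
) -> InstanceMask:
    """Rasterize a worm body as the union of discs along its midline.

    A pixel belongs to the disc of skeleton point i iff its center lies
    within ``halfwidth_profile[i]`` of that point. One-pixel line segments
    between consecutive (rounded) skeleton points are always included, so
    the mask stays connected even at zero half-width, where it degenerates
    to the rasterized midline.
    """
    skeleton = np.asarray(skeleton, dtype=float)
    if skeleton.ndim != 2 or skeleton.shape[0] < 2 or skeleton.shape[1] != 2:
        raise ValueError("skeleton must contain at least 2 (x, y) points")
    profile = np.asarray(halfwidth_profile, dtype=float)
    if profile.shape[0] != skeleton.shape[0]:
        raise ValueError("halfwidth_profile must match skeleton length")

    H, W = image_shape
    pad = int(np.ceil(profile.max())) + 1
    x_min = max(int(np.floor(skeleton[:, 0].min())) - pad, 0)
    y_min = max(int(np.floor(skeleton[:, 1].min())) - pad, 0)
    x_max = min(int(np.ceil(skeleton[:, 0].max())) + pad, W - 1)
    y_max = min(int(np.ceil(skeleton[:, 1].max())) + pad, H - 1)
    local = np.zeros((y_max - y_min + 1, x_max - x_min + 1), dtype=bool)

    for (x, y), hw in zip(skeleton, profile):
        r = int(np.ceil(hw))
        cx, cy = x - x_min, y - y_min
        ix0 = max(int(np.floor(cx)) - r, 0)
        iy0 = max(int(np.floor(cy)) - r, 0)
        ix1 = min(int(np.ceil(cx)) + r, local.shape[1] - 1)
        iy1 = min(int(np.ceil(cy)) + r, local.shape[0] - 1)
        if ix1 < ix0 or iy1 < iy0:
            continue
        yy, xx = np.mgrid[iy0 : iy1 + 1, ix0 : ix1 + 1]
        local[iy0 : iy1 + 1, ix0 : ix1 + 1] |= (
            (xx - cx) ** 2 + (yy - cy) ** 2 <= hw**2
        )

    pts = np.round(skeleton).astype(int)
    pts[:, 0] = np.clip(pts[:, 0], 0, W - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, H - 1)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(y0 - y_min, x0 - x_min, y1 - y_min, x1 - x_min)
        keep = (rr >= 0) & (rr < local.shape[0]) & (cc >= 0) & (cc < local.shape[1])
        local[rr[keep], cc[keep]] = True

    return InstanceMask(local, x0=x_min, y0=y_min)


def _walk_skeleton(
    rng: np.random.Generator,
    length: int,
    center: tuple[int, int],
    max_radius: float,
    turn_sigma: float,
) -> np.ndarray:
    """Unit-step random-heading walk confined to a disc around ``center``."""
    cx, cy = center
    r0 = max_radius * np.sqrt(rng.uniform(0.0, 0.9))
    a0 = rng.uniform(0.0, 2 * np.pi)
    x, y = cx + r0 * np.cos(a0), cy + r0 * np.sin(a0)
    heading = rng.uniform(0.0, 2 * np.pi)
    pts = [(x, y)]
    for _ in range(length - 1):
        heading += rng.normal(0.0, turn_sigma)
        nx, ny = x + np.cos(heading), y + np.sin(heading)
        if (nx - cx) ** 2 + (ny - cy) ** 2 > max_radius**2:
            # steer back toward the dish center, keep a little wiggle
            heading = np.arctan2(cy - y, cx - x) + rng.normal(0.0, 0.3)
            nx, ny = x + np.cos(heading), y + np.sin(heading)
        x, y = nx, ny
        pts.append((x, y))
    return np.asarray(pts)


def generate_dish_image(config: SynthConfig) -> tuple[np.ndarray, list[InstanceMask]]:
    """Render one synthetic plate and its per-worm ground-truth masks.

    Returns
    -------
    image : (H, W) uint8
        Grayscale plate image.
    masks : list of InstanceMask
        Exactly ``config.n_worms`` masks, in the image coordinate frame,
        in generation order. Deterministic given ``config`` (incl. seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    W, H = config.image_width, config.image_height
    cx, cy = config.resolved_center()
    radius = config.resolved_radius()

    yy, xx = np.mgrid[0:H, 0:W]
    dist2 = (xx - cx) ** 2 + (yy - cy) ** 2
    image = np.full((H, W), float(config.outside_level))
    image[dist2 <= (radius + config.rim_width) ** 2] = config.rim_level
    image[dist2 <= radius**2] = config.background_level

    # usable region keeps full worm bodies strictly inside the dish circle
    safe_radius = radius * (1.0 - config.containment_margin) - config.worm_halfwidth - 3.0
    if config.n_worms > 0 and safe_radius <= 0:
        raise ValueError("dish_radius too small to contain worms")

    occupancy = np.zeros((H, W), dtype=bool)
    masks: list[InstanceMask] = []
    worms: list[WormInstance] = []
    for _ in range(config.n_worms):
        for _attempt in range(200):
            length = int(rng.integers(config.worm_length_range[0], config.worm_length_range[1] + 1))
            skel = _walk_skeleton(rng, length, (cx, cy), safe_radius, config.turn_sigma)
            profile = _halfwidth_profile(length, config.worm_halfwidth)
            mask = render_worm(skel, profile, (H, W))
            if config.allow_overlap or not _collides(mask, occupancy, margin=3):
                break
        else:
            raise RuntimeError("could not place a non-overlapping worm; lower n_worms")
        _paint(image, mask, config.worm_level)
        _mark(occupancy, mask)
        masks.append(mask)
        worms.append(WormInstance(skel, profile, mask))

    blob_safe = radius * (1.0 - config.containment_margin) - 2.0
    for _ in range(config.n_blobs):
        for _attempt in range(200):
            br = rng.uniform(*config.blob_radius_range)
            rr = (blob_safe - br) * np.sqrt(rng.uniform())
            aa = rng.uniform(0.0, 2 * np.pi)
            bx, by = cx + rr * np.cos(aa), cy + rr * np.sin(aa)
            blob = _disc_mask(bx, by, br, (H, W))
            if blob is None:
                continue
            # blobs never touch worms: keeps ground truth uncorrupted
            if not _collides(blob, occupancy, margin=3):
                break
        else:
            continue  # plate too crowded for this blob; skip it
        _paint(image, blob, config.blob_level)
        _mark(occupancy, blob)

    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8), masks


def _disc_mask(cx: float, cy: float, r: float, shape: tuple[int, int]) -> InstanceMask | None:
    H, W = shape
    x0, x1 = int(np.floor(cx - r)) - 1, int(np.ceil(cx + r)) + 1
    y0, y1 = int(np.floor(cy - r)) - 1, int(np.ceil(cy + r)) + 1
    if x0 < 0 or y0 < 0 or x1 >= W or y1 >= H:
        return None
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    pix = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if not pix.any():
        return None
    return InstanceMask(pix, x0=x0, y0=y0)


def _paint(image: np.ndarray, mask: InstanceMask, level: float) -> None:
    x0, y0, x1, y1 = mask.bbox
    region = image[y0:y1, x0:x1]
    region[mask.pixels] = level


def _mark(occupancy: np.ndarray, mask: InstanceMask) -> None:
    x0, y0, x1, y1 = mask.bbox
    occupancy[y0:y1, x0:x1] |= mask.pixels


def _collides(mask: InstanceMask, occupancy: np.ndarray, margin: int = 0) -> bool:
    x0, y0, x1, y1 = mask.bbox
    H, W = occupancy.shape
    gx0, gy0 = max(x0 - margin, 0), max(y0 - margin, 0)
    gx1, gy1 = min(x1 + margin, W), min(y1 + margin, H)
    if not occupancy[gy0:gy1, gx0:gx1].any():
        return False
    pix = mask.pixels
    if margin > 0:
        pix = binary_dilation(np.pad(pix, margin), np.ones((3, 3), bool), iterations=margin)
    sub = occupancy[gy0 : gy0 + pix.shape[0], gx0 : gx0 + pix.shape[1]]
    h = min(sub.shape[0], pix.shape[0])
    w = min(sub.shape[1], pix.shape[1])
    return bool((sub[:h, :w] & pix[:h, :w]).any())


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    image: np.ndarray,
    masks: list[InstanceMask],
    out_dir: str | Path,
    config: SynthConfig | None = None,
) -> Path:
    """Write image, per-instance mask PNGs and a JSON manifest; return its path.

    Manifest schema::

        {"image_file": "image.png",
         "instances": [{"id": 0, "bbox": [x0, y0, w, h], "area": int,
                        "mask_file": "mask_000.png"}, ...],
         "config": {...} | null, "seed": int | null}
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / "image.png", image)
    instances = []
    for i, mask in enumerate(masks):
        name = f"mask_{i:03d}.png"
        iio.imwrite(out_dir / name, mask.to_full(image.shape[:2]).astype(np.uint8) * 255)
        instances.append(
            {"id": i, "bbox": list(mask.bbox_xywh), "area": mask.area, "mask_file": name}
        )
    manifest = {
        "image_file": "image.png",
        "instances": instances,
        "config": dataclasses.asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_fixture(manifest_path: str | Path) -> tuple[np.ndarray, list[InstanceMask], dict]:
    """Inverse of :func:`write_fixture`."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    image = iio.imread(base / manifest["image_file"])
    masks = [
        InstanceMask(iio.imread(base / inst["mask_file"]) > 0)
        for inst in manifest["instances"]
    ]
    return image, masks, manifest
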