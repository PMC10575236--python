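"""Dataset-construction augmentation for labeled belt imagery.

Two techniques target crowded frames where not every fish could be
labeled: background blurring (labeled instances preserved bit-exactly,
everything else Gaussian-blurred) and empty-belt replacement (unlabeled
pixels replaced by the same coordinates of a randomly chosen empty-belt
image).  Each image receives exactly one of the two, chosen by a Bernoulli
draw (default p = 0.5), so the training set never shows an unlabeled fish.

A separate geometric/photometric menu (flips, bounded rotation,
brightness/contrast, additive noise, optional blur) transforms raster and
polygons consistently.  Every operation is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LabeledImage, PolygonMask

__all__ = [
    "AugmentationConfig",
    "blur_background",
    "replace_background",
    "sample_technique",
    "augment_geometric_photometric",
]

MIN_INSTANCE_AREA = 4.0  # px^2; clipped instances below this are dropped


@dataclass(frozen=True)
class AugmentationConfig:
    technique_probability: float = 0.5  # P(blur); else empty-belt replacement
    blur_sigma: float = 8.0
    flip_horizontal_p: float = 0.5
    flip_vertical_p: float = 0.5
    max_rotation_deg: float = 30.0
    brightness_delta: tuple[float, float] = (0.0, 0.0)  # additive, intensity units
    contrast_factor: tuple[float, float] = (1.0, 1.0)  # multiplicative about 127.5
    noise_sigma: float = 0.0
    final_blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.technique_probability <= 1.0):
            raise ValueError("technique_probability must lie in [0, 1]")


def _composite(base: np.ndarray, overlay: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = overlay.copy()
    out[mask] = base[mask]
    return out


def blur_background(img: LabeledImage, sigma: float = 8.0) -> LabeledImage:
    """Gaussian-blur everything outside the labeled polygons.

    The blur is computed on the full image and the labeled pixels are then
    composited back, so instance pixels are bit-identical to the input and
    no blurred halo is computed from a hole.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    blurred = np.empty_like(img.image)
    for c in range(3):
        blurred[:, :, c] = ndimage.gaussian_filter(
            img.image[:, :, c], sigma=sigma, mode="nearest"
        )
    out = _composite(img.image, blurred, img.instance_mask())
    return LabeledImage(out, list(img.instances), image_id=img.image_id)


def replace_background(
    img: LabeledImage, belt_pool: list[np.ndarray], seed: int = 0
) -> LabeledImage:
    """Replace all unlabeled pixels with the same coordinates of an empty-belt
    image drawn uniformly from the pool (center-cropped if larger)."""
    if not belt_pool:
        raise ValueError("belt pool is empty")
    rng = np.random.default_rng(seed)
    belt = np.asarray(belt_pool[int(rng.integers(len(belt_pool)))])
    h, w = img.image.shape[:2]
    bh, bw = belt.shape[:2]
    if bh < h or bw < w:
        raise ValueError(f"belt image {bw}x{bh} smaller than target {w}x{h}")
    top, left = (bh - h) // 2, (bw - w) // 2
    belt = belt[top : top + h, left : left + w]
    out = _composite(img.image, belt.astype(np.uint8), img.instance_mask())
    return LabeledImage(out, list(img.instances), image_id=img.image_id)


def sample_technique(cfg: AugmentationConfig, seed: int) -> str:
    """Choose 'blur' or 'replace' by a Bernoulli(technique_probability) draw."""
    rng = np.random.default_rng(seed)
    return "blur" if rng.random() < cfg.technique_probability else "replace"


def _rotation_matrix(angle_deg: float, cx: float, cy: float) -> np.ndarray:
    """Forward 3x3 matrix rotating (x, y) by angle_deg CCW about (cx, cy)."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    to_origin = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=np.float64)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=np.float64)
    back = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=np.float64)
    return back @ rot @ to_origin


def _transform_vertices(m: np.ndarray, verts) -> tuple[tuple[float, float], ...]:
    pts = np.array([[x, y, 1.0] for x, y in verts]).T
    out = m @ pts
    return tuple((float(x), float(y)) for x, y in zip(out[0], out[1]))


def augment_geometric_photometric(
    img: LabeledImage, cfg: AugmentationConfig, seed: int
) -> LabeledImage:
    """Flips, rotation, brightness/contrast, noise and optional blur.

    Polygon vertices receive exactly the geometric map applied to the
    raster; polygons are clipped to bounds after rotation and instances
    whose clipped area drops below 4 px^2 are removed.
    """
    rng = np.random.default_rng(seed)
    h, w = img.image.shape[:2]
    cx, cy = w / 2.0, h / 2.0

    flip_h = rng.random() < cfg.flip_horizontal_p
    flip_v = rng.random() < cfg.flip_vertical_p
    angle = float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    brightness = float(rng.uniform(*cfg.brightness_delta))
    contrast = float(rng.uniform(*cfg.contrast_factor))

    raster = img.image
    m = np.eye(3)
    if flip_h:
        raster = raster[:, ::-1, :]
        m = np.array([[-1, 0, w], [0, 1, 0], [0, 0, 1]], dtype=np.float64) @ m
    if flip_v:
        raster = raster[::-1, :, :]
        m = np.array([[1, 0, 0], [0, -1, h], [0, 0, 1]], dtype=np.float64) @ m
    if angle != 0.0:
        # ndimage.rotate(angle) moves content the way a clockwise rotation of
        # (x, y) coordinates about the image center does, so the polygon map
        # uses -angle about (w/2, h/2).
        raster = ndimage.rotate(
            raster, angle, reshape=False, order=1, mode="constant", cval=0
        )
        m = _rotation_matrix(-angle, cx, cy) @ m

    arr = raster.astype(np.float64)
    if contrast != 1.0:
        arr = (arr - 127.5) * contrast + 127.5
    if brightness != 0.0:
        arr = arr + brightness
    if cfg.noise_sigma > 0:
        arr = arr + rng.normal(0.0, cfg.noise_sigma, size=arr.shape)
    arr = np.clip(arr, 0, 255)
    out = arr.astype(np.uint8)
    if cfg.final_blur_sigma > 0:
        for c in range(3):
            out[:, :, c] = ndimage.gaussian_filter(
                out[:, :, c], sigma=cfg.final_blur_sigma, mode="nearest"
            )

    instances = []
    for poly, name in img.instances:
        moved = PolygonMask(_transform_vertices(m, poly.vertices))
        bb = moved.bounding_box()
        in_bounds = bb.x_min >= 0 and bb.y_min >= 0 and bb.x_max <= w and bb.y_max <= h
        clipped = moved if in_bounds else moved.clipped(w, h)
        if clipped is not None and clipped.area >= MIN_INSTANCE_AREA:
            instances.append((clipped, name))
    return LabeledImage(out, instances, image_id=img.image_id)
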