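"""Inference preprocessing: channel order, letterbox resize, normalization.

The letterbox resize preserves aspect ratio with a single scale factor
``min(target_w/src_w, target_h/src_h)`` and pads the remainder with a
constant gray value, splitting odd remainders so the extra pixel lands on
the bottom/right.  The returned transform is invertible on coordinates so
detections made on the square detector input can be reported in original
image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .core import BoundingBox

__all__ = ["LetterboxTransform", "to_rgb", "letterbox", "unletterbox_box", "normalize"]

DEFAULT_PAD_VALUE = 114  # conventional mid-gray letterbox fill


@dataclass(frozen=True)
class LetterboxTransform:
    scale: float
    pad_left: int
    pad_top: int
    target_size: tuple[int, int]  # (width, height)
    source_size: tuple[int, int]  # (width, height)


def to_rgb(image: np.ndarray) -> np.ndarray:
    """Swap channels 0 and 2 of a 3-channel raster (BGR -> RGB)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected a 3-channel raster, got shape {img.shape}")
    return img[:, :, ::-1].copy()


def letterbox(
    image: np.ndarray,
    target: tuple[int, int] = (640, 640),
    pad_value: int = DEFAULT_PAD_VALUE,
) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize into ``target`` (width, height) with padding.

    Content is resized with bilinear interpolation by the single scale
    factor; padding is filled with ``pad_value``.
    """
    img = np.asarray(image)
    tw, th = int(target[0]), int(target[1])
    if tw <= 0 or th <= 0:
        raise ValueError("target dimensions must be > 0")
    if img.ndim not in (2, 3):
        raise ValueError("image must be 2-D or 3-D")
    sh, sw = img.shape[:2]
    if sh == 0 or sw == 0:
        raise ValueError("source image has a zero dimension")

    scale = min(tw / sw, th / sh)
    cw, ch = max(1, round(sw * scale)), max(1, round(sh * scale))
    pad_left = (tw - cw) // 2
    pad_top = (th - ch) // 2

    resized = np.asarray(
        Image.fromarray(img).resize((cw, ch), resample=Image.BILINEAR)
    )
    if img.ndim == 3:
        out = np.full((th, tw, img.shape[2]), pad_value, dtype=img.dtype)
        out[pad_top : pad_top + ch, pad_left : pad_left + cw, :] = resized
    else:
        out = np.full((th, tw), pad_value, dtype=img.dtype)
        out[pad_top : pad_top + ch, pad_left : pad_left + cw] = resized
    t = LetterboxTransform(
        scale=scale,
        pad_left=pad_left,
        pad_top=pad_top,
        target_size=(tw, th),
        source_size=(sw, sh),
    )
    return out, t


def letterbox_box(box: BoundingBox, t: LetterboxTransform) -> BoundingBox:
    """Map a source-frame box into the letterboxed frame."""
    return BoundingBox(
        box.x_min * t.scale + t.pad_left,
        box.y_min * t.scale + t.pad_top,
        box.x_max * t.scale + t.pad_left,
        box.y_max * t.scale + t.pad_top,
    )


def unletterbox_box(box: BoundingBox, t: LetterboxTransform) -> BoundingBox:
    """Map a letterboxed-frame box back to source coordinates, clipped.

    A box lying entirely inside the padding region cannot correspond to any
    source content and raises.
    """
    sw, sh = t.source_size
    x0 = (box.x_min - t.pad_left) / t.scale
    y0 = (box.y_min - t.pad_top) / t.scale
    x1 = (box.x_max - t.pad_left) / t.scale
    y1 = (box.y_max - t.pad_top) / t.scale
    x0c, x1c = max(0.0, min(x0, sw)), max(0.0, min(x1, sw))
    y0c, y1c = max(0.0, min(y0, sh)), max(0.0, min(y1, sh))
    if x1c <= x0c or y1c <= y0c:
        raise ValueError("box lies entirely in the padding region; impossible detection")
    return BoundingBox(x0c, y0c, x1c, y1c)


def normalize(image: np.ndarray) -> np.ndarray:
    """Scale an 8-bit raster to floating point values in [0, 1]."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError(f"expected an 8-bit image, got dtype {img.dtype}")
    return img.astype(np.float64) / 255.0
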