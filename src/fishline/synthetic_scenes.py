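"""Synthetic conveyor-belt scenes with exactly known ground truth.

Fish are rendered as rotated capsules (rectangle with semicircular ends)
in a species-specific hue on a textured gray belt.  The capsule polygon,
its tight bounding box and the species label are recorded per instance,
so detector, postprocessing, morphometrics and evaluation can all be
exercised without any real imagery.  ``perturb_detections`` corrupts the
ground truth with controlled miss/false-positive/confusion/jitter rates to
emulate an imperfect detector.

Default species frequencies are proportional to the labeled-sample counts
of the first monitored plant (anchovy 549, jack mackerel 1339, mackerel
139, sardine 480); default lengths respect the small (< 20 cm) versus
large (> 20 cm) species split so the size filter is meaningfully
exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .core import (
    BoundingBox,
    CameraCalibration,
    Detection,
    LabeledImage,
    PolygonMask,
    SpeciesCatalog,
    box_iou,
    default_catalog,
)

__all__ = [
    "SceneConfig",
    "PerturbationConfig",
    "generate_scene",
    "generate_empty_belt",
    "perturb_detections",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_LENGTHS_CM",
]

BELT_TONE = (95, 95, 100)

# Relative frequencies proportional to the labeled-sample counts of the
# first plant's four target species.
DEFAULT_FREQUENCIES = {
    "anchovy": 549.0,
    "jack_mackerel": 1339.0,
    "mackerel": 139.0,
    "sardine": 480.0,
}

# (mean, sd) total length in cm; small species < 20 cm, large species > 20 cm.
# Means follow typical adult sizes of the landed species (anchoveta ~12 cm,
# common sardine ~13 cm, jack mackerel and chub mackerel ~30 cm).
DEFAULT_LENGTHS_CM = {
    "anchovy": (12.0, 1.2),
    "jack_mackerel": (30.0, 3.0),
    "mackerel": (30.0, 3.0),
    "sardine": (13.0, 1.3),
    "jumbo_squid": (60.0, 6.0),
    "snoek": (70.0, 7.0),
}


@dataclass(frozen=True)
class SceneConfig:
    image_size: tuple[int, int] = (1920, 1080)  # (width, height)
    belt_tone: tuple[int, int, int] = BELT_TONE
    frequencies: dict = field(default_factory=lambda: dict(DEFAULT_FREQUENCIES))
    lengths_cm: dict = field(default_factory=lambda: dict(DEFAULT_LENGTHS_CM))
    cm_per_pixel: float = 0.05
    instance_count: tuple[int, int] = (3, 8)  # inclusive range
    overlap_fraction: float = 0.0  # max allowed pairwise box IoU
    aspect_ratio: float = 0.25  # body width / body length of the capsule
    texture_sigma: float = 6.0  # belt texture amplitude, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = list(self.frequencies.values())
        if not freqs or any(f < 0 for f in freqs) or sum(freqs) <= 0:
            raise ValueError("frequencies must be nonnegative with a positive sum")
        if any(m <= 0 or s < 0 for m, s in self.lengths_cm.values()):
            raise ValueError("length distributions must have positive means")


@dataclass(frozen=True)
class PerturbationConfig:
    miss_rate: float = 0.0
    fp_rate: float = 0.0  # expected spurious detections per frame
    confusion_rates: dict = field(default_factory=dict)  # {(true, pred): p}
    box_jitter_sd: float = 0.0  # px
    tp_confidence: tuple[float, float] = (0.85, 0.05)  # (mean, sd)
    fp_confidence: tuple[float, float] = (0.4, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must lie in [0, 1]")
        if self.fp_rate < 0 or self.box_jitter_sd < 0:
            raise ValueError("rates must be nonnegative")
        for p in self.confusion_rates.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("confusion rates must lie in [0, 1]")


def _belt_raster(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = cfg.image_size
    base = np.empty((h, w, 3), dtype=np.float64)
    base[:] = cfg.belt_tone
    # low-frequency streaks along the belt direction plus per-pixel grain
    streaks = rng.normal(0.0, cfg.texture_sigma, size=(h, 1, 1))
    grain = rng.normal(0.0, cfg.texture_sigma / 2.0, size=(h, w, 1))
    return np.clip(base + streaks + grain, 0, 255).astype(np.uint8)


def _capsule_polygon(
    cx: float, cy: float, length_px: float, width_px: float, angle_rad: float, n_arc: int = 10
) -> tuple[tuple[float, float], ...]:
    """Capsule (stadium) outline of given total length/width, rotated."""
    r = width_px / 2.0
    half = max(length_px / 2.0 - r, 1e-6)
    pts = []
    # right semicircle from -90 to +90 deg, then left from +90 to 270 deg
    for i in range(n_arc + 1):
        t = -math.pi / 2 + math.pi * i / n_arc
        pts.append((half + r * math.cos(t), r * math.sin(t)))
    for i in range(n_arc + 1):
        t = math.pi / 2 + math.pi * i / n_arc
        pts.append((-half + r * math.cos(t), r * math.sin(t)))
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return tuple((cx + x * c - y * s, cy + x * s + y * c) for x, y in pts)


def _shade(color: tuple[int, int, int], rng: np.random.Generator) -> tuple[int, int, int]:
    f = float(rng.uniform(0.9, 1.1))
    return tuple(int(np.clip(round(v * f), 0, 255)) for v in color)


def generate_scene(
    cfg: SceneConfig,
    seed: int,
    catalog: SpeciesCatalog | None = None,
    frame_id: str | None = None,
) -> tuple[LabeledImage, list[Detection]]:
    """Render one scene; returns the labeled image and confidence-1 truths.

    Placement uses rejection sampling: a candidate is accepted only if its
    box IoU with every placed instance is at most ``overlap_fraction`` and
    the capsule fits inside the frame.  Failure to place after 10,000
    rejections is a hard error (the requested density is infeasible).
    """
    if catalog is None:
        catalog, _ = default_catalog()
    rng = np.random.default_rng(seed)
    w, h = cfg.image_size
    frame_id = frame_id if frame_id is not None else f"scene-{seed}"

    belt = _belt_raster(cfg, rng)
    img = Image.fromarray(belt)
    draw = ImageDraw.Draw(img)

    names = [n for n in cfg.frequencies if cfg.frequencies[n] > 0]
    probs = np.array([cfg.frequencies[n] for n in names], dtype=np.float64)
    probs /= probs.sum()

    lo, hi = cfg.instance_count
    count = int(rng.integers(lo, hi + 1))
    placed_boxes: list[BoundingBox] = []
    instances: list[tuple[PolygonMask, str]] = []
    truths: list[Detection] = []
    attempts = 0
    while len(truths) < count:
        # species is drawn once per instance so the realized species mix is
        # exactly multinomial in the configured weights; placement rejection
        # retries length/position only.
        species = str(rng.choice(names, p=probs))
        mean, sd = cfg.lengths_cm[species]
        while True:
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError(
                    "could not place requested instance count; lower the density "
                    "(fewer instances, smaller fish, or higher overlap_fraction)"
                )
            length_cm = max(1.0, float(rng.normal(mean, sd)))
            length_px = length_cm / cfg.cm_per_pixel
            width_px = max(2.0, length_px * cfg.aspect_ratio)
            angle = float(rng.uniform(0, math.pi))
            margin = length_px / 2.0 + 2
            if 2 * margin >= min(w, h):
                continue  # fish longer than the frame; redraw length/angle
            cx = float(rng.uniform(margin, w - margin))
            cy = float(rng.uniform(margin, h - margin))
            poly = PolygonMask(_capsule_polygon(cx, cy, length_px, width_px, angle))
            box = poly.bounding_box()
            if any(box_iou(box, pb) > cfg.overlap_fraction for pb in placed_boxes):
                continue
            break
        color = _shade(catalog[species].display_color, rng)
        draw.polygon([(x, y) for x, y in poly.vertices], fill=color)
        placed_boxes.append(box)
        instances.append((poly, species))
        truths.append(
            Detection(
                box=box,
                mask=poly,
                species=species,
                confidence=1.0,
                frame_id=frame_id,
            )
        )
    labeled = LabeledImage(np.asarray(img), instances, image_id=frame_id)
    return labeled, truths


def generate_empty_belt(cfg: SceneConfig, seed: int) -> np.ndarray:
    """Belt texture only; the pool source for background replacement."""
    rng = np.random.default_rng(seed)
    return _belt_raster(cfg, rng)


def perturb_detections(
    truths: list[Detection],
    cfg: PerturbationConfig,
    seed: int,
    catalog: SpeciesCatalog | None = None,
    image_size: tuple[int, int] = (1920, 1080),
) -> list[Detection]:
    """Corrupt ground truth into a synthetic detector output.

    Each truth is independently dropped with ``miss_rate``; survivors get
    Gaussian box jitter, a possible species flip per ``confusion_rates``
    (keyed by (true, predicted) ordered pairs) and a truncated-normal
    confidence.  Poisson(``fp_rate``) spurious boxes with the false-positive
    confidence model are appended per frame.
    """
    if catalog is None:
        catalog, _ = default_catalog()
    rng = np.random.default_rng(seed)
    w, h = image_size
    out: list[Detection] = []
    frames: list[str] = []
    for t in truths:
        if t.frame_id not in frames:
            frames.append(t.frame_id)
    for t in truths:
        if rng.random() < cfg.miss_rate:
            continue
        b = t.box
        if cfg.box_jitter_sd > 0:
            j = rng.normal(0.0, cfg.box_jitter_sd, size=4)
            x0 = min(max(0.0, b.x_min + j[0]), w - 2.0)
            y0 = min(max(0.0, b.y_min + j[1]), h - 2.0)
            x1 = max(x0 + 1.0, min(float(w), b.x_max + j[2]))
            y1 = max(y0 + 1.0, min(float(h), b.y_max + j[3]))
            b = BoundingBox(x0, y0, x1, y1)
        species = t.species
        u = rng.random()
        acc = 0.0
        for (true_s, pred_s), p in sorted(cfg.confusion_rates.items()):
            if true_s != t.species:
                continue
            acc += p
            if u < acc:
                species = pred_s
                break
        conf = float(np.clip(rng.normal(*cfg.tp_confidence), 0.01, 1.0))
        out.append(
            Detection(box=b, species=species, confidence=conf, frame_id=t.frame_id)
        )
    names = list(catalog.names)
    for frame in frames or ["frame-0"]:
        for _ in range(int(rng.poisson(cfg.fp_rate))):
            bw = float(rng.uniform(20, 200))
            bh = float(rng.uniform(20, 200))
            x0 = float(rng.uniform(0, max(1.0, w - bw)))
            y0 = float(rng.uniform(0, max(1.0, h - bh)))
            conf = float(np.clip(rng.normal(*cfg.fp_confidence), 0.01, 1.0))
            out.append(
                Detection(
                    box=BoundingBox(x0, y0, x0 + bw, y0 + bh),
                    species=str(rng.choice(names)),
                    confidence=conf,
                    frame_id=frame,
                )
            )
    return out
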