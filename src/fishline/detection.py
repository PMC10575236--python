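"""Pluggable detector contract plus a reference heuristic detector.

The trained network that performs fish discrimination in production is
deliberately outside this package; any detector that emits the JSON-lines
detection dialect can be plugged in through the ``external-command``
backend.  The ``reference`` backend is a self-contained color-segmentation
detector tuned to the synthetic scene palette (species-distinct hues on a
gray belt) so the full pipeline runs end-to-end without trained weights.

The reference detector letterboxes its input to the configured square
size, segments foreground by chromatic distance from the estimated belt
tone, labels connected components, assigns each component the nearest
palette hue, and reports boxes mapped back to original image coordinates.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BoundingBox, Detection, SpeciesCatalog
from .preprocessing import letterbox, unletterbox_box

__all__ = ["DetectorConfig", "detect", "reference_detect"]


@dataclass(frozen=True)
class DetectorConfig:
    backend: str = "reference"  # "reference" or "command:<executable>"
    confidence_floor: float = 0.25
    input_size: tuple[int, int] = (640, 640)

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_floor <= 1.0):
            raise ValueError("confidence_floor must lie in [0, 1]")


def detect(
    image: np.ndarray,
    cfg: DetectorConfig,
    catalog: SpeciesCatalog,
    frame_id: str = "frame-0",
) -> list[Detection]:
    """Run the configured backend; detections come back in source coordinates
    with confidence >= the configured floor."""
    if cfg.backend == "reference":
        dets = reference_detect(image, catalog, frame_id=frame_id, input_size=cfg.input_size)
    elif cfg.backend.startswith("command:"):
        dets = _command_detect(image, cfg.backend.split(":", 1)[1], catalog, frame_id)
    else:
        raise ValueError(f"unknown detector backend {cfg.backend!r}")
    h, w = np.asarray(image).shape[:2]
    out = []
    for d in dets:
        if d.confidence < cfg.confidence_floor:
            continue
        b = d.box
        box = BoundingBox(
            min(max(0.0, b.x_min), w - 1.0),
            min(max(0.0, b.y_min), h - 1.0),
            max(1.0, min(float(w), b.x_max)),
            max(1.0, min(float(h), b.y_max)),
        )
        out.append(d.replace(box=box))
    return out


MIN_COMPONENT_PX = 40  # components smaller than this are sensor noise


def reference_detect(
    image: np.ndarray,
    catalog: SpeciesCatalog,
    frame_id: str = "frame-0",
    input_size: tuple[int, int] = (640, 640),
) -> list[Detection]:
    """Color-segmentation detector for synthetic-palette scenes.

    Deterministic: no randomness anywhere.  Confidence is the mean
    color-match score of the component against its assigned palette color,
    mapped into [0, 1].
    """
    img = np.asarray(image, dtype=np.uint8)
    boxed, t = letterbox(img, input_size)
    arr = boxed.astype(np.float64)

    # The belt dominates the content region; estimate its tone by the median.
    content = arr[t.pad_top : t.pad_top + round(t.source_size[1] * t.scale),
                  t.pad_left : t.pad_left + round(t.source_size[0] * t.scale)]
    belt_tone = np.median(content.reshape(-1, 3), axis=0)

    dist_belt = np.linalg.norm(arr - belt_tone, axis=2)
    foreground = dist_belt > 45.0
    foreground = ndimage.binary_opening(foreground, structure=np.ones((2, 2)))
    labels, n = ndimage.label(foreground)
    if n == 0:
        return []

    palette = np.array([c.display_color for c in catalog], dtype=np.float64)
    dets: list[Detection] = []
    for sl_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels[sl] == sl_idx
        if comp.sum() < MIN_COMPONENT_PX:
            continue
        mean_color = arr[sl][comp].mean(axis=0)
        d = np.linalg.norm(palette - mean_color, axis=1)
        k = int(np.argmin(d))
        # match score: 1 at exact palette color, 0 at distance >= 255
        score = float(np.clip(1.0 - d[k] / 255.0, 0.0, 1.0))
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        try:
            box = unletterbox_box(BoundingBox(x0, y0, x1, y1), t)
        except ValueError:
            continue  # component entirely in padding: impossible
        dets.append(
            Detection(
                box=box,
                species=catalog.classes[k].name,
                confidence=score,
                frame_id=frame_id,
            )
        )
    dets.sort(key=lambda d: -d.confidence)
    return dets


def _command_detect(
    image: np.ndarray, executable: str, catalog: SpeciesCatalog, frame_id: str
) -> list[Detection]:
    """Invoke an external detector: PNG on stdin, JSON-lines on stdout."""
    import io
    from PIL import Image

    buf = io.BytesIO()
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(buf, format="PNG")
    proc = subprocess.run(
        [executable], input=buf.getvalue(), capture_output=True
    )
    if proc.returncode != 0:
        raise RuntimeError(
            f"external detector {executable!r} failed "
            f"(exit {proc.returncode}): {proc.stderr.decode(errors='replace')}"
        )
    dets = []
    for line in proc.stdout.decode().splitlines():
        if line.strip():
            rec = json.loads(line)
            rec.setdefault("frame_id", frame_id)
            det = Detection.from_record(rec)
            if det.species not in catalog:
                raise ValueError(f"external detector emitted unknown species {det.species!r}")
            dets.append(det)
    return dets
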