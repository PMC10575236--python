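"""Detection postprocessing: size-based discard, multiclass NMS, rendering.

The stages run in pipeline order.  The size filter removes implausible
detections: small-bodied species (sardine, anchovy) estimated longer than
20 cm and large-bodied species (jack mackerel, mackerel) estimated shorter
than 20 cm.  The multiclass non-maximum suppression is class-agnostic:
overlapping boxes compete on confidence regardless of their labels, which
resolves the double-label failure mode where one fish receives boxes of
two species.  Rendering strokes each surviving box in its species color
with the label, confidence and optional length/weight annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .core import BoundingBox, CameraCalibration, Detection, SpeciesCatalog, box_iou
from .morphometrics import Morphometry, estimate_length

__all__ = [
    "NmsConfig",
    "SizeFilterRule",
    "rules_from_catalog",
    "size_filter",
    "multiclass_nms",
    "render_annotations",
]


@dataclass(frozen=True)
class NmsConfig:
    """IoU threshold above which two boxes are considered the same object."""

    iou_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class SizeFilterRule:
    """Discard rule for one species.

    ``discard_if_longer``: detections with estimated length above
    ``threshold_cm`` are discarded (small-bodied species);
    ``discard_if_shorter``: detections below it are discarded.
    """

    species: str
    kind: str  # discard_if_longer | discard_if_shorter
    threshold_cm: float

    def __post_init__(self) -> None:
        if self.kind not in ("discard_if_longer", "discard_if_shorter"):
            raise ValueError(f"unknown size filter kind {self.kind!r}")
        if self.threshold_cm <= 0:
            raise ValueError("threshold must be > 0")

    def violates(self, length_cm: float) -> bool:
        if self.kind == "discard_if_longer":
            return length_cm > self.threshold_cm
        return length_cm < self.threshold_cm


def rules_from_catalog(catalog: SpeciesCatalog) -> list[SizeFilterRule]:
    """Translate catalog size rules into filter rules."""
    rules = []
    for cls in catalog:
        if cls.size_rule is None:
            continue
        kind, thr = cls.size_rule
        rules.append(
            SizeFilterRule(
                species=cls.name,
                kind="discard_if_longer" if kind == "max_length_cm" else "discard_if_shorter",
                threshold_cm=thr,
            )
        )
    return rules


def size_filter(
    dets: list[Detection],
    rules: list[SizeFilterRule],
    cal: CameraCalibration,
) -> tuple[list[Detection], list[Detection]]:
    """Partition detections into (kept, discarded) by the species size rules.

    Species without a rule are always kept.  Input order is preserved in
    both partitions.
    """
    by_species = {r.species: r for r in rules}
    kept: list[Detection] = []
    discarded: list[Detection] = []
    for det in dets:
        rule = by_species.get(det.species)
        if rule is not None and rule.violates(estimate_length(det.box, cal)):
            discarded.append(det)
        else:
            kept.append(det)
    return kept, discarded


def multiclass_nms(dets: list[Detection], cfg: NmsConfig = NmsConfig()) -> list[Detection]:
    """Greedy class-agnostic non-maximum suppression.

    Detections are visited in descending confidence (ties broken by input
    order, earlier wins); one is accepted iff its IoU with every already
    accepted detection — of any class — is below the threshold.  The output
    is sorted by descending confidence and the operation is idempotent.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    accepted: list[Detection] = []
    for i in order:
        cand = dets[i]
        if all(box_iou(cand.box, a.box) < cfg.iou_threshold for a in accepted):
            accepted.append(cand)
    return accepted


def render_annotations(
    image: np.ndarray,
    dets: list[Detection],
    catalog: SpeciesCatalog,
    morph_results: list[Morphometry | None] | None = None,
    line_width: int = 3,
) -> np.ndarray:
    """Draw boxes, labels and optional measurements; input is not mutated."""
    for det in dets:
        if det.species not in catalog:
            raise KeyError(f"species {det.species!r} not in catalog")
    canvas = Image.fromarray(np.asarray(image, dtype=np.uint8).copy())
    draw = ImageDraw.Draw(canvas)
    for k, det in enumerate(dets):
        color = tuple(catalog[det.species].display_color)
        b = det.box
        draw.rectangle(
            [b.x_min, b.y_min, b.x_max - 1, b.y_max - 1], outline=color, width=line_width
        )
        label = f"{det.species} {det.confidence:.2f}"
        draw.text((b.x_min + 2, max(0, b.y_min - 12)), label, fill=color)
        if morph_results is not None and morph_results[k] is not None:
            m = morph_results[k]
            txt = f"{m.length_cm:.1f}cm"
            if m.weight_g is not None:
                txt += f"/{m.weight_g:.0f}g"
            draw.text((b.x_min + 2, min(canvas.height - 10, b.y_max + 2)), txt, fill=color)
    return np.asarray(canvas)
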