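"""Detection evaluation: matching, confusion matrix, MP, AP and mAP.

Matching is greedy and one-to-one per frame: detections in descending
confidence order each claim the highest-IoU unconsumed ground truth at or
above the IoU threshold, regardless of class, so cross-class confusions
are representable.  The confusion matrix carries an explicit background
row and column: an unmatched detection counts against (predicted class,
background) — a false positive on empty belt — and an unmatched truth
against (background, true class) — a missed fish.

Macro-average precision (MP) is the unweighted mean of the per-class
diagonal of the column-normalized confusion matrix:

    MP = (PC_1 + PC_2 + ... + PC_N) / N

Average precision (AP) is the area under the all-point interpolated
(monotone envelope) precision-recall curve of one class, with matching
restricted to that class; mAP is the mean of the per-class APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BoundingBox, Detection, PolygonMask, SpeciesCatalog, box_iou

__all__ = [
    "MatchConfig",
    "GroundTruth",
    "MatchResult",
    "ConfusionMatrix",
    "PrecisionReport",
    "APReport",
    "match_detections",
    "confusion_matrix",
    "macro_precision",
    "average_precision",
    "mean_average_precision",
    "evaluate",
]

BACKGROUND = "__background__"


@dataclass(frozen=True)
class MatchConfig:
    iou_threshold: float = 0.45
    use_masks: bool = False  # mask IoU when both masks are present

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    box: BoundingBox
    species: str
    frame_id: str = "frame-0"
    mask: PolygonMask | None = None

    @classmethod
    def from_detection(cls, d: Detection) -> "GroundTruth":
        return cls(box=d.box, species=d.species, frame_id=d.frame_id, mask=d.mask)


@dataclass
class MatchResult:
    pairs: list[tuple[Detection, GroundTruth]] = field(default_factory=list)
    unmatched_detections: list[Detection] = field(default_factory=list)
    unmatched_truths: list[GroundTruth] = field(default_factory=list)


def _mask_iou(a: PolygonMask, b: PolygonMask) -> float:
    pa, pb = a.to_shapely(), b.to_shapely()
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def _pair_iou(det: Detection, truth: GroundTruth, cfg: MatchConfig) -> float:
    if cfg.use_masks and det.mask is not None and truth.mask is not None:
        return _mask_iou(det.mask, truth.mask)
    return box_iou(det.box, truth.box)


def match_detections(
    dets: list[Detection],
    truths: list[GroundTruth | Detection],
    cfg: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Greedy one-to-one matching per frame (class-agnostic)."""
    truths = [
        t if isinstance(t, GroundTruth) else GroundTruth.from_detection(t)
        for t in truths
    ]
    result = MatchResult()
    frames: list[str] = []
    for x in list(dets) + list(truths):
        if x.frame_id not in frames:
            frames.append(x.frame_id)
    for frame in frames:
        fdets = [d for d in dets if d.frame_id == frame]
        ftruths = [t for t in truths if t.frame_id == frame]
        order = sorted(range(len(fdets)), key=lambda i: (-fdets[i].confidence, i))
        consumed = [False] * len(ftruths)
        for i in order:
            det = fdets[i]
            best_j, best_iou = -1, cfg.iou_threshold
            for j, t in enumerate(ftruths):
                if consumed[j]:
                    continue
                iou = _pair_iou(det, t, cfg)
                if iou > best_iou or (iou == best_iou and iou >= cfg.iou_threshold and best_j < 0):
                    best_j, best_iou = j, iou
            if best_j >= 0:
                consumed[best_j] = True
                result.pairs.append((det, ftruths[best_j]))
            else:
                result.unmatched_detections.append(det)
        result.unmatched_truths.extend(
            t for j, t in enumerate(ftruths) if not consumed[j]
        )
    return result


class ConfusionMatrix:
    """(N+1) x (N+1) counts: rows = predicted class + background, columns =
    true class + background.  Cell (background, background) is identically 0."""

    def __init__(self, catalog: SpeciesCatalog):
        self.catalog = catalog
        n = len(catalog)
        self.counts = np.zeros((n + 1, n + 1), dtype=np.int64)

    @property
    def background_index(self) -> int:
        return len(self.catalog)

    def normalized(self) -> np.ndarray:
        """Column-normalized view; all-zero columns stay zero."""
        out = self.counts.astype(np.float64)
        sums = out.sum(axis=0, keepdims=True)
        nonzero = sums > 0
        out = np.divide(out, sums, where=nonzero, out=np.zeros_like(out))
        return out


def confusion_matrix(matches: MatchResult, catalog: SpeciesCatalog) -> ConfusionMatrix:
    cm = ConfusionMatrix(catalog)
    bg = cm.background_index
    for det, truth in matches.pairs:
        cm.counts[catalog.index(det.species), catalog.index(truth.species)] += 1
    for det in matches.unmatched_detections:
        cm.counts[catalog.index(det.species), bg] += 1
    for truth in matches.unmatched_truths:
        cm.counts[bg, catalog.index(truth.species)] += 1
    return cm


@dataclass(frozen=True)
class PrecisionReport:
    per_class_precision: tuple[float, ...]
    MP: float
    class_names: tuple[str, ...] = ()

    @classmethod
    def from_precisions(
        cls, values, class_names: tuple[str, ...] = ()
    ) -> "PrecisionReport":
        vals = tuple(float(v) for v in values)
        return cls(vals, float(np.mean(vals)), class_names)


def macro_precision(cm: ConfusionMatrix) -> PrecisionReport:
    """Per-class precision from the column-normalized diagonal, and their mean.

    A class whose column is empty (the class never occurs as truth or
    prediction target) has undefined precision and raises.
    """
    n = len(cm.catalog)
    col_sums = cm.counts[:, :n].sum(axis=0)
    empty = [cm.catalog.names[i] for i in range(n) if col_sums[i] == 0]
    if empty:
        raise ValueError(f"no counts in class column(s): {empty}; precision undefined")
    norm = cm.normalized()
    per_class = tuple(float(norm[i, i]) for i in range(n))
    return PrecisionReport.from_precisions(per_class, cm.catalog.names)


@dataclass(frozen=True)
class APReport:
    per_class_ap: dict
    mAP: float
    curves: dict  # class -> (recall array, precision array)


def average_precision(
    dets: list[Detection],
    truths: list[GroundTruth | Detection],
    species: str,
    cfg: MatchConfig = MatchConfig(),
) -> tuple[float, np.ndarray, np.ndarray]:
    """AP of one class: area under the monotone-envelope PR curve.

    Matching is restricted to the class (standard detector evaluation).
    Returns (ap, recall points, envelope precision points).
    """
    truths = [
        t if isinstance(t, GroundTruth) else GroundTruth.from_detection(t)
        for t in truths
    ]
    cls_truths = [t for t in truths if t.species == species]
    if not cls_truths:
        raise ValueError(f"no ground truths of class {species!r}")
    cls_dets = sorted(
        (d for d in dets if d.species == species),
        key=lambda d: -d.confidence,
    )
    n_truth = len(cls_truths)
    consumed: set[int] = set()
    tp = np.zeros(len(cls_dets))
    for i, det in enumerate(cls_dets):
        best_j, best_iou = -1, cfg.iou_threshold
        for j, t in enumerate(cls_truths):
            if j in consumed or t.frame_id != det.frame_id:
                continue
            iou = _pair_iou(det, t, cfg)
            if iou > best_iou or (iou == best_iou and best_j < 0):
                best_j, best_iou = j, iou
        if best_j >= 0:
            consumed.add(best_j)
            tp[i] = 1.0
    if len(cls_dets) == 0:
        return 0.0, np.array([0.0]), np.array([0.0])
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(cls_dets) + 1)
    recall = cum_tp / n_truth
    # monotone envelope: precision at recall r is max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    # integrate over recall steps
    r_prev = 0.0
    ap = 0.0
    for p, r in zip(env, recall):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap), recall, env


def mean_average_precision(per_class_ap: dict, catalog: SpeciesCatalog) -> float:
    missing = [n for n in catalog.names if n not in per_class_ap]
    if missing:
        raise ValueError(f"missing AP for class(es): {missing}")
    return float(np.mean([per_class_ap[n] for n in catalog.names]))


def evaluate(
    dets: list[Detection],
    truths: list[GroundTruth | Detection],
    catalog: SpeciesCatalog,
    cfg: MatchConfig = MatchConfig(),
) -> dict:
    """Full report: confusion matrix, per-class precision, MP, per-class AP
    and mAP, over the classes that occur as ground truth."""
    truths = [
        t if isinstance(t, GroundTruth) else GroundTruth.from_detection(t)
        for t in truths
    ]
    matches = match_detections(dets, truths, cfg)
    cm = confusion_matrix(matches, catalog)
    present = [n for n in catalog.names if any(t.species == n for t in truths)]
    report: dict = {"confusion_matrix": cm}
    if present:
        # per-class precision over the classes that occur as ground truth:
        # each has a nonempty column (a matched pair or a background miss).
        norm = cm.normalized()
        per_class = {n: float(norm[catalog.index(n), catalog.index(n)]) for n in present}
        report["per_class_precision"] = per_class
        report["MP"] = float(np.mean(list(per_class.values())))
    aps: dict = {}
    curves: dict = {}
    for name in present:
        ap, rec, prec = average_precision(dets, truths, name, cfg)
        aps[name] = ap
        curves[name] = (rec, prec)
    if aps:
        report["per_class_ap"] = aps
        report["mAP"] = float(np.mean(list(aps.values())))
        report["curves"] = curves
    return report
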