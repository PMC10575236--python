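"""Matching, confusion matrix with background semantics, MP, AP and mAP."""

import numpy as np
import pytest

from fishline.core import BoundingBox, Detection, SpeciesCatalog, SpeciesClass, box_iou
from fishline.evaluation import (
    BACKGROUND,
    ConfusionMatrix,
    GroundTruth,
    MatchConfig,
    PrecisionReport,
    average_precision,
    confusion_matrix,
    evaluate,
    macro_precision,
    match_detections,
    mean_average_precision,
)


def det(x0, y0, x1, y1, species, conf, frame="f"):
    return Detection(BoundingBox(x0, y0, x1, y1), species, conf, frame_id=frame)


def truth(x0, y0, x1, y1, species, frame="f"):
    return GroundTruth(BoundingBox(x0, y0, x1, y1), species, frame_id=frame)


def cm_from_columns(catalog, columns):
    """Build a confusion matrix whose class columns hold the given count
    vectors (length N+1, last entry = background-FN row)."""
    cm = ConfusionMatrix(catalog)
    for j, col in enumerate(columns):
        for i, c in enumerate(col):
            cm.counts[i, j] = c
    return cm


@pytest.fixture(scope="module")
def plant2_catalog():
    return SpeciesCatalog(
        [SpeciesClass(n) for n in ("jack_mackerel", "mackerel", "jumbo_squid", "snoek")]
    )


class TestMatching:
    def test_single_pair_above_threshold(self):
        m = match_detections(
            [det(0, 0, 10, 10, "sardine", 0.9)], [truth(0, 0, 10, 11, "sardine")]
        )
        assert len(m.pairs) == 1
        assert not m.unmatched_detections and not m.unmatched_truths

    def test_one_to_one_highest_confidence_wins(self):
        d1 = det(0, 0, 10, 10, "sardine", 0.9)
        d2 = det(0, 0, 10, 9, "sardine", 0.8)
        m = match_detections([d2, d1], [truth(0, 0, 10, 10, "sardine")])
        assert m.pairs == [(d1, truth(0, 0, 10, 10, "sardine"))]
        assert m.unmatched_detections == [d2]

    def test_below_threshold_is_background(self):
        m = match_detections(
            [det(0, 0, 10, 10, "sardine", 0.9)],
            [truth(8, 8, 20, 20, "sardine")],
            MatchConfig(iou_threshold=0.45),
        )
        assert not m.pairs
        assert len(m.unmatched_detections) == 1 and len(m.unmatched_truths) == 1

    def test_class_agnostic_matching(self):
        m = match_detections(
            [det(0, 0, 10, 10, "mackerel", 0.9)], [truth(0, 0, 10, 10, "jack_mackerel")]
        )
        assert len(m.pairs) == 1  # cross-class confusion is representable

    def test_matches_exhaustive_greedy_oracle_on_random_frames(self, catalog):
        rng = np.random.default_rng(21)
        cfg = MatchConfig(iou_threshold=0.3)
        for _ in range(10):
            frame_dets, frame_truths = [], []
            for f in range(3):
                fid = f"frame-{f}"
                for _ in range(int(rng.integers(0, 8))):
                    x0, y0 = rng.uniform(0, 150, 2)
                    frame_truths.append(
                        truth(x0, y0, x0 + rng.uniform(10, 60), y0 + rng.uniform(10, 60),
                              str(rng.choice(catalog.names)), fid)
                    )
                for _ in range(int(rng.integers(0, 8))):
                    x0, y0 = rng.uniform(0, 150, 2)
                    frame_dets.append(
                        det(x0, y0, x0 + rng.uniform(10, 60), y0 + rng.uniform(10, 60),
                            str(rng.choice(catalog.names)), float(rng.random()), fid)
                    )
            got = match_detections(frame_dets, frame_truths, cfg)
            # oracle: explicit per-frame greedy enumeration, dict-based
            pairs, unmatched_d, consumed = [], [], set()
            frames = {d.frame_id for d in frame_dets} | {t.frame_id for t in frame_truths}
            for fid in sorted(frames):
                ds = [d for d in frame_dets if d.frame_id == fid]
                ts = [(j, t) for j, t in enumerate(frame_truths) if t.frame_id == fid]
                for d in sorted(ds, key=lambda d: -d.confidence):
                    cands = [
                        (box_iou(d.box, t.box), j, t)
                        for j, t in ts
                        if j not in consumed and box_iou(d.box, t.box) >= cfg.iou_threshold
                    ]
                    if cands:
                        iou, j, t = max(cands, key=lambda c: c[0])
                        consumed.add(j)
                        pairs.append((d, t))
                    else:
                        unmatched_d.append(d)
            assert sorted(got.pairs, key=lambda p: -p[0].confidence) == sorted(
                pairs, key=lambda p: -p[0].confidence
            )
            assert set(got.unmatched_detections) == set(unmatched_d)
            assert len(got.unmatched_truths) == len(frame_truths) - len(pairs)


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self, catalog):
        dets = [det(i * 30, 0, i * 30 + 20, 20, "sardine", 0.9) for i in range(3)]
        truths = [truth(i * 30, 0, i * 30 + 20, 20, "sardine") for i in range(3)]
        cm = confusion_matrix(match_detections(dets, truths), catalog)
        assert cm.counts.sum() == 3
        assert cm.counts[catalog.index("sardine"), catalog.index("sardine")] == 3

    def test_missed_truth_counts_as_background_fn(self, catalog):
        dets = [det(0, 0, 20, 20, "sardine", 0.9)]
        truths = [truth(0, 0, 20, 20, "sardine"), truth(100, 100, 120, 120, "sardine")]
        cm = confusion_matrix(match_detections(dets, truths), catalog)
        j = catalog.index("sardine")
        assert cm.counts[j, j] == 1
        assert cm.counts[cm.background_index, j] == 1
        norm = cm.normalized()
        assert norm[j, j] == pytest.approx(0.5)
        assert norm[cm.background_index, j] == pytest.approx(0.5)

    def test_spurious_detection_counts_as_background_fp(self, catalog):
        dets = [det(0, 0, 20, 20, "mackerel", 0.9)]
        cm = confusion_matrix(match_detections(dets, []), catalog)
        assert cm.counts[catalog.index("mackerel"), cm.background_index] == 1

    def test_empty_inputs_all_zero(self, catalog):
        cm = confusion_matrix(match_detections([], []), catalog)
        assert cm.counts.sum() == 0
        assert cm.counts[cm.background_index, cm.background_index] == 0

    def test_normalized_columns_sum_to_one(self, catalog):
        rng = np.random.default_rng(22)
        dets, truths = [], []
        for k in range(40):
            x0, y0 = rng.uniform(0, 400, 2)
            sp = str(rng.choice(catalog.names))
            truths.append(truth(x0, y0, x0 + 20, y0 + 20, sp, f"fr-{k % 4}"))
            if rng.random() < 0.8:
                dets.append(det(x0 + 1, y0, x0 + 21, y0 + 20, sp, float(rng.random()), f"fr-{k % 4}"))
        cm = confusion_matrix(match_detections(dets, truths), catalog)
        norm = cm.normalized()
        sums = cm.counts.sum(axis=0)
        for j in range(norm.shape[1]):
            if sums[j] > 0:
                assert norm[:, j].sum() == pytest.approx(1.0)


class TestMacroPrecision:
    def test_plant2_diagonal_values(self, plant2_catalog):
        # columns of 100 truths each with the observed diagonal rates
        cm = cm_from_columns(
            plant2_catalog,
            [
                [98, 1, 0, 0, 1],
                [2, 84, 0, 10, 4],
                [0, 0, 100, 0, 0],
                [0, 30, 0, 40, 30],
            ],
        )
        report = macro_precision(cm)
        assert report.per_class_precision == pytest.approx((0.98, 0.84, 1.0, 0.4))
        assert report.MP == pytest.approx(0.805, abs=1e-12)

    def test_plant1_diagonal_values(self, plant2_catalog):
        report = PrecisionReport.from_precisions((0.9, 0.93, 0.95, 0.83))
        assert report.MP == pytest.approx(0.9025, abs=1e-12)
        assert round(report.MP, 1) == 0.9

    def test_all_perfect_gives_one(self, plant2_catalog):
        cm = cm_from_columns(plant2_catalog, [[10, 0, 0, 0, 0], [0, 7, 0, 0, 0],
                                              [0, 0, 4, 0, 0], [0, 0, 0, 9, 0]])
        assert macro_precision(cm).MP == 1.0

    def test_empty_column_is_hard_error_naming_class(self, plant2_catalog):
        cm = cm_from_columns(plant2_catalog, [[10, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="mackerel"):
            macro_precision(cm)


def ap_oracle(dets, truths, species, threshold):
    """O(n^2) independent AP: explicit TP flags, explicit suffix-max envelope,
    explicit step integration."""
    cls_t = [t for t in truths if t.species == species]
    cls_d = sorted([d for d in dets if d.species == species], key=lambda d: -d.confidence)
    used = set()
    flags = []
    for d in cls_d:
        best = None
        for j, t in enumerate(cls_t):
            if j in used or t.frame_id != d.frame_id:
                continue
            iou = box_iou(d.box, t.box)
            if iou >= threshold and (best is None or iou > best[0]):
                best = (iou, j)
        if best is not None:
            used.add(best[1])
            flags.append(1)
        else:
            flags.append(0)
    n_t = len(cls_t)
    points = []
    tp = 0
    for k, f in enumerate(flags, start=1):
        tp += f
        points.append((tp / n_t, tp / k))
    ap = 0.0
    r_prev = 0.0
    for k, (r, _) in enumerate(points):
        if r > r_prev:
            p_env = max(p for rr, p in points[k:])
            ap += (r - r_prev) * p_env
            r_prev = r
    return ap


class TestAveragePrecision:
    def test_single_correct_detection(self):
        ap, _, _ = average_precision(
            [det(0, 0, 10, 10, "sardine", 0.9)], [truth(0, 0, 10, 10, "sardine")], "sardine"
        )
        assert ap == 1.0

    def test_fp_above_tp_halves_ap(self):
        dets = [
            det(100, 100, 120, 120, "sardine", 0.9),  # FP, nothing there
            det(0, 0, 10, 10, "sardine", 0.8),  # TP
        ]
        ap, recall, env = average_precision(dets, [truth(0, 0, 10, 10, "sardine")], "sardine")
        assert ap == pytest.approx(0.5)

    def test_zero_truths_is_hard_error(self):
        with pytest.raises(ValueError):
            average_precision([det(0, 0, 10, 10, "sardine", 0.9)], [], "sardine")

    def test_equals_brute_force_oracle(self, catalog):
        rng = np.random.default_rng(23)
        cfg = MatchConfig(iou_threshold=0.4)
        for _ in range(50):
            dets, truths = [], []
            for _ in range(int(rng.integers(1, 10))):
                x0, y0 = rng.uniform(0, 200, 2)
                truths.append(truth(x0, y0, x0 + 25, y0 + 25, "sardine", f"fr-{int(rng.integers(2))}"))
            for _ in range(int(rng.integers(0, 15))):
                x0, y0 = rng.uniform(0, 200, 2)
                dets.append(det(x0, y0, x0 + 25, y0 + 25, "sardine",
                                float(rng.random()), f"fr-{int(rng.integers(2))}"))
            ap, _, _ = average_precision(dets, truths, "sardine", cfg)
            assert ap == pytest.approx(ap_oracle(dets, truths, "sardine", 0.4), abs=1e-9)

    def test_invariant_to_monotone_confidence_transform(self):
        rng = np.random.default_rng(24)
        dets, truths = [], []
        for k in range(8):
            x0, y0 = rng.uniform(0, 200, 2)
            truths.append(truth(x0, y0, x0 + 25, y0 + 25, "sardine"))
            if rng.random() < 0.7:
                dets.append(det(x0 + 2, y0, x0 + 27, y0 + 25, "sardine", float(rng.uniform(0.2, 0.9))))
        ap1, _, _ = average_precision(dets, truths, "sardine")
        squashed = [d.replace(confidence=d.confidence ** 3) for d in dets]
        ap2, _, _ = average_precision(squashed, truths, "sardine")
        assert ap1 == pytest.approx(ap2, abs=1e-12)


class TestMeanAveragePrecision:
    def test_simple_means(self, plant2_catalog):
        names = plant2_catalog.names
        assert mean_average_precision(dict(zip(names, [1.0, 1.0, 1.0, 1.0])), plant2_catalog) == 1.0
        assert mean_average_precision(dict(zip(names, [1.0, 0.0, 1.0, 0.0])), plant2_catalog) == 0.5

    def test_exact_mean_of_three(self):
        cat = SpeciesCatalog([SpeciesClass(n) for n in "abc"])
        assert mean_average_precision({"a": 0.6, "b": 0.7, "c": 0.8}, cat) == pytest.approx(0.7)

    def test_missing_class_is_hard_error(self, plant2_catalog):
        with pytest.raises(ValueError):
            mean_average_precision({"mackerel": 1.0}, plant2_catalog)


class TestCatalogOrderInvariance:
    def test_mp_and_map_invariant_under_reordering(self, catalog):
        rng = np.random.default_rng(25)
        dets, truths = [], []
        for k in range(60):
            x0, y0 = rng.uniform(0, 500, 2)
            sp = str(rng.choice(["sardine", "anchovy", "mackerel"]))
            truths.append(truth(x0, y0, x0 + 30, y0 + 30, sp, f"fr-{k % 5}"))
            if rng.random() < 0.85:
                pred = sp if rng.random() < 0.9 else "jack_mackerel"
                dets.append(det(x0 + 1, y0 + 1, x0 + 31, y0 + 31, pred,
                                float(rng.random()), f"fr-{k % 5}"))
        r1 = evaluate(dets, truths, catalog)
        shuffled = SpeciesCatalog(list(catalog.classes[::-1]))
        r2 = evaluate(dets, truths, shuffled)
        assert r1["MP"] == pytest.approx(r2["MP"], abs=1e-12)
        assert r1["mAP"] == pytest.approx(r2["mAP"], abs=1e-12)
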