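"""Evaluation metrics: matching rules, PR formulas, AP oracles and the
mAP threshold range."""

import numpy as np
import pytest

from yoloev.boxes import Box
from yoloev.metrics import (IOU_RANGE, DetectionRecord, PRCurve,
                            average_precision, evaluate_detections,
                            map_range, match_detections, mean_ap, pr_curve,
                            precision, recall, read_jsonl, write_jsonl)


def det(img, cls, conf, x1, y1, x2, y2):
    return DetectionRecord(str(img), cls, conf, Box(x1, y1, x2, y2))


# ------------------------------------------------------------- matching
def test_match_single_tp():
    gts = [det(0, 0, 1.0, 0, 0, 10, 10)]
    dets = [det(0, 0, 0.9, 1, 1, 10, 10)]  # IoU ~ 0.81
    assert match_detections(dets, gts, 0.5).tolist() == [True]


def test_match_greedy_consumption():
    gts = [det(0, 0, 1.0, 0, 0, 10, 10)]
    dets = [det(0, 0, 0.6, 0, 0, 10, 9),     # lower confidence
            det(0, 0, 0.9, 0, 0, 9, 10)]     # higher confidence wins the gt
    flags = match_detections(dets, gts, 0.5)
    assert flags.tolist() == [False, True]


def test_match_below_threshold_is_fp():
    gts = [det(0, 0, 1.0, 0, 0, 10, 10)]
    dets = [det(0, 0, 0.9, 0, 0, 10, 4)]     # IoU 0.4
    assert match_detections(dets, gts, 0.5).tolist() == [False]


def test_match_is_class_aware_and_image_aware():
    gts = [det("a", 0, 1.0, 0, 0, 10, 10), det("b", 1, 1.0, 0, 0, 10, 10)]
    dets = [det("a", 1, 0.9, 0, 0, 10, 10),   # wrong class
            det("b", 1, 0.8, 0, 0, 10, 10),   # right image+class
            det("a", 0, 0.7, 0, 0, 10, 10)]
    assert match_detections(dets, gts, 0.5).tolist() == [False, True, True]


# ------------------------------------------------------- P/R formulas
def test_precision_recall_formulas():
    assert precision(8, 2) == 0.8
    assert recall(3, 1) == 0.75
    with pytest.warns(UserWarning):
        assert precision(0, 0) == 0.0
    with pytest.warns(UserWarning):
        assert recall(0, 0) == 0.0


# --------------------------------------------------------------- AP
def test_ap_perfect_detector():
    curve = pr_curve(np.array([1.0, 1.0]), np.array([True, True]), n_gt=2)
    assert average_precision(curve) == 1.0


def test_ap_only_false_positives():
    curve = pr_curve(np.array([0.9, 0.8]), np.array([False, False]), n_gt=3)
    assert average_precision(curve) == 0.0


def test_ap_frozen_envelope_example():
    """Flags [TP, FP, TP] with 2 gts: envelope area 0.5*1 + 0.5*(2/3)."""
    curve = pr_curve(np.array([0.9, 0.8, 0.7]),
                     np.array([True, False, True]), n_gt=2)
    assert np.isclose(average_precision(curve), 5 / 6, atol=1e-9)


def test_ap_undefined_without_ground_truths():
    with pytest.raises(ValueError, match="no ground truths"):
        average_precision(PRCurve(np.array([1.0]), np.array([0.0]), 0))


def _brute_force_ap(conf, flags, n_gt):
    """Independent oracle: explicit threshold sweep building the PR set,
    then exact integration of the non-increasing envelope."""
    pts = []
    for thr in sorted(set(conf)) + [np.inf]:
        sel = conf >= thr if thr is not np.inf else np.zeros_like(flags)
        tp = int((flags & sel).sum())
        fp = int((~flags & sel).sum())
        if tp + fp:
            pts.append((tp / n_gt, tp / (tp + fp)))
    pts.sort()
    rec = np.array([0.0] + [r for r, _ in pts])
    prc = np.array([1.0] + [p for _, p in pts])
    area = 0.0
    for i in range(1, len(rec)):
        area += (rec[i] - rec[i - 1]) * prc[i:].max(initial=prc[i])
    return area


def test_ap_matches_brute_force_threshold_sweep(rng):
    for _ in range(25):
        n = int(rng.integers(3, 30))
        # distinct confidences: a threshold sweep cannot separate ties,
        # which the cumulative curve resolves by documented input order
        conf = rng.permutation(np.linspace(0.05, 0.95, n))
        flags = rng.random(n) > 0.5
        n_gt = int(flags.sum() + rng.integers(0, 4))
        if n_gt == 0:
            continue
        ap = average_precision(pr_curve(conf, flags, n_gt))
        assert np.isclose(ap, _brute_force_ap(conf, flags, n_gt), atol=1e-9)


def test_ap_invariant_to_confidence_rescaling(rng):
    conf = rng.random(20)
    flags = rng.random(20) > 0.4
    a = average_precision(pr_curve(conf, flags, 12))
    b = average_precision(pr_curve(conf * 0.3 + 0.01, flags, 12))
    assert a == b


# --------------------------------------------------------------- mAP
def test_mean_ap():
    assert mean_ap([0.5, 1.0]) == 0.75
    with pytest.raises(ValueError):
        mean_ap([])


def test_map_perfect_detector_over_range(rng):
    gts, dets = [], []
    for i in range(6):
        b = rng.uniform(0, 40, 2)
        box = (b[0], b[1], b[0] + rng.uniform(5, 20), b[1] + rng.uniform(5, 20))
        gts.append(det(i % 2, i % 3, 1.0, *box))
        dets.append(det(i % 2, i % 3, 0.95, *box))
    m50, m5095 = map_range(dets, gts)
    assert m50 == 1.0 and m5095 == 1.0


def test_map_range_has_ten_thresholds_and_ordering(rng):
    assert len(IOU_RANGE) == 10
    assert IOU_RANGE[0] == 0.5 and IOU_RANGE[-1] == 0.95
    # jittered detections: tighter thresholds can only lower the mAP
    gts, dets = [], []
    for i in range(30):
        x, y = rng.uniform(0, 80, 2)
        w, h = rng.uniform(8, 25, 2)
        gts.append(det(i % 4, i % 3, 1.0, x, y, x + w, y + h))
        j = rng.uniform(-2.5, 2.5, 4)
        dets.append(det(i % 4, i % 3, float(rng.random()),
                        x + j[0], y + j[1], x + w + j[2], y + h + j[3]))
    m50, m5095 = map_range(dets, gts)
    assert m5095 <= m50 + 1e-12


def _coco_style_reference(dets, gts, classes):
    """Independent COCO-style evaluator: 101-point interpolation per class,
    written without the package's PR plumbing."""
    aps = []
    for c in classes:
        cls_gts = [g for g in gts if g.class_id == c]
        cls_dets = sorted([d for d in dets if d.class_id == c],
                          key=lambda d: -d.confidence)
        matched = set()
        tps = []
        for d in cls_dets:
            best, best_key = 0.0, None
            for k, g in enumerate(cls_gts):
                if g.image_id != d.image_id or k in matched:
                    continue
                from yoloev.boxes import iou_matrix
                v = iou_matrix(d.box.as_array(), g.box.as_array())[0, 0]
                if v > best:
                    best, best_key = v, k
            if best_key is not None and best >= 0.5:
                matched.add(best_key)
                tps.append(1)
            else:
                tps.append(0)
        tp = np.cumsum(tps)
        fp = np.cumsum([1 - t for t in tps])
        rec = tp / max(len(cls_gts), 1)
        prec = tp / np.maximum(tp + fp, 1)
        ap = 0.0
        for r in np.linspace(0, 1, 101):
            mask = rec >= r
            ap += prec[mask].max() if mask.any() else 0.0
        aps.append(ap / 101)
    return float(np.mean(aps))


def test_matches_independent_coco_style_evaluator(rng):
    """Random 3-class fixture: package mAP@0.5 (101-point mode) agrees with
    an independently coded reference evaluator to 0.01."""
    gts, dets = [], []
    for i in range(60):
        img = str(i % 8)
        x, y = rng.uniform(0, 100, 2)
        w, h = rng.uniform(6, 30, 2)
        c = int(rng.integers(0, 3))
        gts.append(det(img, c, 1.0, x, y, x + w, y + h))
        if rng.random() < 0.85:  # mostly-found gt, jittered
            j = rng.uniform(-3, 3, 4)
            dets.append(det(img, c, float(rng.random()), x + j[0], y + j[1],
                            x + w + j[2], y + h + j[3]))
        if rng.random() < 0.3:   # spurious detection
            dets.append(det(img, int(rng.integers(0, 3)),
                            float(rng.random()), x + 40, y + 40,
                            x + 55, y + 52))
    ours = evaluate_detections(dets, gts, 0.5, interpolation="101point").mAP
    ref = _coco_style_reference(dets, gts, [0, 1, 2])
    assert abs(ours - ref) < 0.01


def test_jsonl_roundtrip(tmp_path, rng):
    recs = [det(i, int(rng.integers(0, 3)), float(rng.random()),
                0, 0, 5 + i, 7 + i) for i in range(5)]
    write_jsonl(recs, tmp_path / "dets.jsonl")
    back = read_jsonl(tmp_path / "dets.jsonl")
    assert back == recs
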