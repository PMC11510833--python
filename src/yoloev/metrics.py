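"""Detection evaluation: precision, recall, average precision and mAP.

Precision = TP/(TP+FP); recall = TP/(TP+FN); AP is the area under the
precision-recall curve traced by sweeping the confidence threshold, and
mAP averages AP over classes.  mAP@0.5:0.95 additionally averages over the
ten IoU matching thresholds 0.50, 0.55, ..., 0.95.

Matching is greedy per class: detections are processed in descending
confidence (ties broken by input order) and each consumes its best-IoU
still-unmatched ground truth of the same class when that IoU reaches the
threshold; otherwise the detection counts as a false positive.

AP uses the all-point interpolation (the non-increasing precision envelope
integrated over recall increments); a 101-point COCO-style grid is
available via ``interpolation="101point"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import Box, iou_matrix

__all__ = ["DetectionRecord", "PRCurve", "APResult", "match_detections",
           "precision", "recall", "pr_curve", "average_precision", "mean_ap",
           "evaluate_detections", "map_range", "read_jsonl", "write_jsonl"]

IOU_RANGE = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))  # 10 thresholds


@dataclass(frozen=True)
class DetectionRecord:
    image_id: str
    class_id: int
    confidence: float
    box: Box

    def __post_init__(self):
        if not np.isfinite(self.confidence):
            raise ValueError("confidence must be finite")


@dataclass
class PRCurve:
    """Cumulative counts in descending-confidence order for one class."""
    tp: np.ndarray
    fp: np.ndarray
    n_gt: int

    @property
    def precisions(self) -> np.ndarray:
        denom = self.tp + self.fp
        return np.where(denom > 0, self.tp / np.maximum(denom, 1), 0.0)

    @property
    def recalls(self) -> np.ndarray:
        if self.n_gt == 0:
            return np.zeros_like(self.tp, dtype=float)
        return self.tp / self.n_gt


@dataclass
class APResult:
    per_class: dict = field(default_factory=dict)

    @property
    def mAP(self) -> float:
        return mean_ap(list(self.per_class.values()))


def precision(tp: int, fp: int) -> float:
    """Formula P = TP/(TP+FP); 0 by convention when undefined."""
    if tp + fp == 0:
        warnings.warn("precision undefined for TP+FP=0; returning 0")
        return 0.0
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """Formula R = TP/(TP+FN); 0 by convention when undefined."""
    if tp + fn == 0:
        warnings.warn("recall undefined for TP+FN=0; returning 0")
        return 0.0
    return tp / (tp + fn)


def _group_by_image(records):
    groups = {}
    for i, r in enumerate(records):
        groups.setdefault(r.image_id, []).append((i, r))
    return groups


def match_detections(dets: list, gts: list, iou_thr: float = 0.5) -> np.ndarray:
    """TP/FP flags for detections against ground truths.

    ``dets`` are :class:`DetectionRecord`; ``gts`` are records whose
    confidence is ignored.  Matching is greedy in descending confidence and
    strictly class-aware.  Returns a boolean array aligned with ``dets``.
    """
    flags = np.zeros(len(dets), dtype=bool)
    gt_groups = _group_by_image(gts)
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].confidence, i))
    used = {img: np.zeros(len(g), dtype=bool) for img, g in gt_groups.items()}
    for i in order:
        d = dets[i]
        cands = gt_groups.get(d.image_id, [])
        best_j, best_iou = -1, 0.0
        for j, (_, g) in enumerate(cands):
            if g.class_id != d.class_id or used[d.image_id][j]:
                continue
            v = iou_matrix(d.box.as_array(), g.box.as_array())[0, 0]
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thr:
            flags[i] = True
            used[d.image_id][best_j] = True
    return flags


def pr_curve(confidences: np.ndarray, tp_flags: np.ndarray,
             n_gt: int) -> PRCurve:
    order = np.argsort(-np.asarray(confidences), kind="stable")
    tp = np.cumsum(np.asarray(tp_flags, dtype=float)[order])
    fp = np.cumsum(~np.asarray(tp_flags, dtype=bool)[order])
    return PRCurve(tp=tp, fp=fp, n_gt=n_gt)


def average_precision(curve: PRCurve,
                      interpolation: str = "allpoint") -> float:
    """Area under the precision envelope over recall."""
    if curve.n_gt == 0:
        raise ValueError("AP undefined for a class with no ground truths")
    if len(curve.tp) == 0:
        return 0.0
    rec = np.concatenate([[0.0], curve.recalls, [curve.recalls[-1]]])
    prec = np.concatenate([[1.0], curve.precisions, [0.0]])
    # non-increasing envelope
    prec = np.maximum.accumulate(prec[::-1])[::-1]
    if interpolation == "allpoint":
        idx = np.where(rec[1:] != rec[:-1])[0]
        return float(np.sum((rec[idx + 1] - rec[idx]) * prec[idx + 1]))
    if interpolation == "101point":
        grid = np.linspace(0, 1, 101)
        ip = np.array([prec[rec >= g].max() if (rec >= g).any() else 0.0
                       for g in grid])
        return float(ip.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_ap(aps: list) -> float:
    """Arithmetic mean of per-class APs."""
    if not aps:
        raise ValueError("mean AP of an empty class list")
    return float(np.mean(aps))


def evaluate_detections(dets: list, gts: list, iou_thr: float = 0.5,
                        interpolation: str = "allpoint") -> APResult:
    """Per-class AP at one IoU threshold; classes without ground truths are
    excluded from the mean (with a warning if they received detections)."""
    classes = sorted({g.class_id for g in gts})
    det_classes = {d.class_id for d in dets}
    for c in sorted(det_classes - set(classes)):
        warnings.warn(f"class {c} has detections but no ground truths; "
                      "excluded from mAP")
    flags = match_detections(dets, gts, iou_thr)
    result = APResult()
    for c in classes:
        idx = [i for i, d in enumerate(dets) if d.class_id == c]
        n_gt = sum(1 for g in gts if g.class_id == c)
        curve = pr_curve(np.array([dets[i].confidence for i in idx]),
                         flags[idx], n_gt)
        result.per_class[c] = average_precision(curve, interpolation)
    return result


def map_range(dets: list, gts: list,
              interpolation: str = "allpoint") -> tuple:
    """(mAP@0.5, mAP@0.5:0.95) over the ten-threshold range."""
    maps = [evaluate_detections(dets, gts, t, interpolation).mAP
            for t in IOU_RANGE]
    return maps[0], float(np.mean(maps))


# ------------------------------------------------------------------ io
def write_jsonl(records: list, path):
    with open(path, "w") as f:
        for r in records:
            f.write(json.dumps({
                "image_id": r.image_id, "class_id": r.class_id,
                "confidence": r.confidence,
                "box": [r.box.x1, r.box.y1, r.box.x2, r.box.y2]}) + "\n")


def read_jsonl(path) -> list:
    out = []
    with open(path) as f:
        for line in f:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(DetectionRecord(d["image_id"], int(d["class_id"]),
                                       float(d["confidence"]),
                                       Box(*d["box"])))
    return out
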