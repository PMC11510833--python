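"""Axis-aligned bounding boxes and the IoU loss family.

Boxes use the corner convention (x1, y1, x2, y2) in continuous image
coordinates with the origin top-left; half-open, x2 > x1 and y2 > y1.
YOLO-format labels (normalized centre-size) are converted at the I/O
boundary only (see :mod:`yoloev.data`).

The loss family: L = 1 - score with score IoU, GIoU (enclosing-box
penalty), DIoU (centre-distance penalty) or CIoU (aspect-ratio term on top
of DIoU).  All are zero iff the boxes coincide and invariant under joint
translation and uniform scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Box", "iou", "iou_matrix", "box_loss", "xywhn_to_xyxy",
           "xyxy_to_xywhn", "nms"]


@dataclass(frozen=True)
class Box:
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(np.isfinite(vals)):
            raise ValueError(f"box coordinates must be finite, got {vals}")

    @property
    def area(self) -> float:
        return max(self.x2 - self.x1, 0.0) * max(self.y2 - self.y1, 0.0)

    @property
    def center(self) -> tuple:
        return ((self.x1 + self.x2) / 2, (self.y1 + self.y2) / 2)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


def _as_box(b) -> Box:
    return b if isinstance(b, Box) else Box(*b)


def iou(a, b) -> float:
    """Intersection over union of two boxes; degenerate boxes overlap 0."""
    a, b = _as_box(a), _as_box(b)
    if a.area == 0 or b.area == 0:
        warnings.warn("degenerate (zero-area) box in IoU; returning 0")
        return 0.0
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) and (M,4) corner-format arrays -> (N,M)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - \
        np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - \
        np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def box_loss(a, b, variant: str = "iou") -> float:
    """IoU-family regression loss 1 - score for a pair of boxes."""
    a, b = _as_box(a), _as_box(b)
    i = iou(a, b)
    if variant == "iou":
        return 1.0 - i
    ex1, ey1 = min(a.x1, b.x1), min(a.y1, b.y1)
    ex2, ey2 = max(a.x2, b.x2), max(a.y2, b.y2)
    if variant == "giou":
        enclose = (ex2 - ex1) * (ey2 - ey1)
        inter = max(min(a.x2, b.x2) - max(a.x1, b.x1), 0) * \
            max(min(a.y2, b.y2) - max(a.y1, b.y1), 0)
        union = a.area + b.area - inter
        return 1.0 - (i - (enclose - union) / max(enclose, 1e-12))
    (acx, acy), (bcx, bcy) = a.center, b.center
    d2 = (acx - bcx) ** 2 + (acy - bcy) ** 2
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    if variant == "diou":
        return 1.0 - (i - d2 / max(c2, 1e-12))
    if variant == "ciou":
        wa, ha = a.x2 - a.x1, a.y2 - a.y1
        wb, hb = b.x2 - b.x1, b.y2 - b.y1
        v = (4 / np.pi ** 2) * (np.arctan(wb / hb) - np.arctan(wa / ha)) ** 2
        alpha = v / max(1 - i + v, 1e-12)
        return 1.0 - (i - d2 / max(c2, 1e-12) - alpha * v)
    raise ValueError(f"unknown IoU variant {variant!r}")


def xywhn_to_xyxy(boxes: np.ndarray, w: float, h: float) -> np.ndarray:
    """Normalized centre-size -> pixel corner format."""
    b = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    cx, cy, bw, bh = b[:, 0] * w, b[:, 1] * h, b[:, 2] * w, b[:, 3] * h
    return np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=1)


def xyxy_to_xywhn(boxes: np.ndarray, w: float, h: float) -> np.ndarray:
    """Pixel corner -> normalized centre-size format."""
    b = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    return np.stack([(b[:, 0] + b[:, 2]) / 2 / w, (b[:, 1] + b[:, 3]) / 2 / h,
                     (b[:, 2] - b[:, 0]) / w, (b[:, 3] - b[:, 1]) / h], axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.6) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[ious <= iou_thr]
    return np.array(keep, dtype=np.int64)
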