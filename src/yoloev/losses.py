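"""Bounding-box regression losses and the composite detection loss.

The box term is Wise-IoU (v3 form): the plain IoU loss is scaled by a
distance-attention factor

    R = exp( ((cx_p - cx_g)^2 + (cy_p - cy_g)^2) / (cw^2 + ch^2)* )

with (cw, ch) the enclosing-box extent and * marking a gradient-detached
denominator, and then by a dynamic non-monotonic gain.  Each box's outlier
degree is beta = L_IoU* / running_mean (both detached), where the running
mean of the IoU loss is tracked by an exponential moving average during
training; the gain

    r = beta / (delta * alpha^(beta - delta))

peaks at beta = delta (r = 1) and decays towards zero for both very good
(beta -> 0) and very poor (beta -> inf) boxes, focusing gradient on
medium-quality anchors.

The composite loss pairs predictions with ground truth through a
task-aligned top-k assigner and sums a weighted Wise-IoU box term, binary
cross-entropy on task-aligned class scores, and a distribution-focal term
over the reg_max box bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .blocks import Detect
from .boxes import Box, iou_matrix

__all__ = ["WIoUState", "wiou_loss", "wiou_loss_batch",
           "TaskAlignedAssigner", "DetectionLoss"]


@dataclass
class WIoUState:
    """Running state of the Wise-IoU focusing mechanism.

    ``momentum`` is the EMA weight of the *new* batch mean (the reference
    default corresponds to 1/(2*10^3) per update).
    """
    running_mean: float = 1.0
    momentum: float = 5e-4
    alpha: float = 1.9
    delta: float = 3.0
    updates: int = 0

    def gain(self, liou_detached: np.ndarray) -> np.ndarray:
        """Non-monotonic gradient gain r(beta) for detached IoU losses."""
        mean = self.running_mean
        if mean <= 0:
            beta = np.ones_like(np.asarray(liou_detached, dtype=np.float64))
        else:
            beta = np.asarray(liou_detached, dtype=np.float64) / mean
        return beta / (self.delta * self.alpha ** (beta - self.delta))

    def update(self, liou_detached: np.ndarray):
        batch = float(np.mean(liou_detached))
        if self.updates == 0:
            self.running_mean = batch
        else:
            self.running_mean = (1 - self.momentum) * self.running_mean + \
                self.momentum * batch
        self.updates += 1


def wiou_loss(pred, gt, state: WIoUState, training: bool = False):
    """Scalar Wise-IoU loss and gain for a single box pair."""
    pred = pred if isinstance(pred, Box) else Box(*pred)
    gt = gt if isinstance(gt, Box) else Box(*gt)
    a, b = pred.as_array(), gt.as_array()
    i = iou_matrix(a, b)[0, 0]
    liou = 1.0 - i
    (pcx, pcy), (gcx, gcy) = pred.center, gt.center
    d2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    r_att = math.exp(d2 / max(cw ** 2 + ch ** 2, 1e-12))
    gain = float(state.gain(np.array([liou]))[0])
    if training:
        state.update(np.array([liou]))
    return gain * r_att * liou, gain


def wiou_loss_batch(pred: Tensor, gt: np.ndarray, state: WIoUState,
                    training: bool = True):
    """Differentiable Wise-IoU over (N,4) predicted corner boxes.

    Returns (per-pair loss Tensor (N,), gains ndarray).  The focusing gain,
    the outlier degree and the distance-attention denominator are all
    treated as constants for the gradient, matching the detachment contract.
    """
    gt = np.asarray(gt, dtype=np.float32)
    px1, py1 = pred.narrow(1, 0, 1), pred.narrow(1, 1, 1)
    px2, py2 = pred.narrow(1, 2, 1), pred.narrow(1, 3, 1)
    gx1, gy1, gx2, gy2 = (gt[:, i:i + 1] for i in range(4))
    iw = Tensor.minimum(px2, gx2) - Tensor.maximum(px1, gx1)
    ih = Tensor.minimum(py2, gy2) - Tensor.maximum(py1, gy1)
    inter = iw.clamp(0, None) * ih.clamp(0, None)
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter
    iou_t = inter / (union + 1e-9)
    liou = 1.0 - iou_t                                   # (N,1)
    dx = (px1 + px2) * 0.5 - (gx1 + gx2) * 0.5
    dy = (py1 + py2) * 0.5 - (gy1 + gy2) * 0.5
    d2 = dx * dx + dy * dy
    cw = Tensor.maximum(px2, gx2) - Tensor.minimum(px1, gx1)
    ch = Tensor.maximum(py2, gy2) - Tensor.minimum(py1, gy1)
    diag2 = (cw * cw + ch * ch).detach() + 1e-9          # gradient-detached
    r_att = (d2 / diag2).exp()
    liou_det = liou.data[:, 0].copy()
    gains = state.gain(liou_det).astype(np.float32)
    if training:
        state.update(liou_det)
    loss = (r_att * liou).reshape(-1) * Tensor(gains)
    return loss, gains


class TaskAlignedAssigner:
    """Top-k task-aligned matching of anchors to ground-truth boxes.

    Alignment metric: score(gt class)^alpha * IoU^beta over anchors whose
    centre lies inside the box; the k best per ground truth are candidates,
    conflicts resolve to the highest-IoU ground truth.  Target class scores
    are the per-anchor metric normalised so each ground truth's best anchor
    gets its best IoU.
    """

    def __init__(self, topk: int = 10, alpha: float = 0.5, beta: float = 6.0):
        self.topk, self.alpha, self.beta = topk, alpha, beta

    def __call__(self, scores: np.ndarray, pboxes: np.ndarray,
                 anchors: np.ndarray, gt_cls: np.ndarray,
                 gt_boxes: np.ndarray):
        """Single image.  scores (A,nc) in [0,1]; pboxes/gt_boxes corner px.

        Returns (fg_mask (A,), gt_idx (A,), target_scores (A,nc)).
        """
        a, nc = scores.shape
        fg = np.zeros(a, dtype=bool)
        gt_idx = np.zeros(a, dtype=np.int64)
        tscores = np.zeros((a, nc), dtype=np.float32)
        m = len(gt_boxes)
        if m == 0:
            return fg, gt_idx, tscores
        ious = iou_matrix(gt_boxes, pboxes)                       # (M,A)
        inside = ((anchors[None, :, 0] > gt_boxes[:, None, 0]) &
                  (anchors[None, :, 0] < gt_boxes[:, None, 2]) &
                  (anchors[None, :, 1] > gt_boxes[:, None, 1]) &
                  (anchors[None, :, 1] < gt_boxes[:, None, 3]))
        cls_score = scores[:, gt_cls.astype(int)].T               # (M,A)
        metric = (cls_score ** self.alpha) * (ious ** self.beta)
        metric = np.where(inside, metric, 0.0)
        cand = np.zeros_like(inside)
        k = min(self.topk, a)
        topk_idx = np.argpartition(-metric, k - 1, axis=1)[:, :k]
        rows = np.repeat(np.arange(m), k)
        cols = topk_idx.ravel()
        ok = metric[rows, cols] > 0
        cand[rows[ok], cols[ok]] = True
        # resolve anchors claimed by several ground truths: keep best IoU
        masked_iou = np.where(cand, ious, -1.0)
        best_gt = masked_iou.argmax(axis=0)
        fg = masked_iou.max(axis=0) > -1.0
        gt_idx = best_gt
        # normalised target scores
        pos_metric = np.where(cand, metric, 0.0)
        amax = pos_metric.max(axis=1, keepdims=True)              # (M,1)
        imax = np.where(cand, ious, 0.0).max(axis=1, keepdims=True)
        norm = pos_metric * imax / (amax + 1e-9)                  # (M,A)
        for anchor in np.flatnonzero(fg):
            g = gt_idx[anchor]
            tscores[anchor, int(gt_cls[g])] = norm[g, anchor]
        return fg, gt_idx, tscores


class DetectionLoss:
    """Composite detector loss: Wise-IoU box + BCE class + distribution
    focal box-bin terms, weighted 7.5 : 0.5 : 1.5."""

    def __init__(self, model, box_w: float = 7.5, cls_w: float = 0.5,
                 dfl_w: float = 1.5, wiou: WIoUState | None = None,
                 assigner: TaskAlignedAssigner | None = None,
                 box_variant: str = "wiou"):
        self.model = model
        self.nc = model.cfg.nc
        self.reg_max = model.cfg.reg_max
        self.strides = list(model.cfg.strides)
        self.weights = (box_w, cls_w, dfl_w)
        self.wiou = wiou or WIoUState()
        self.assigner = assigner or TaskAlignedAssigner()
        self.box_variant = box_variant
        self.proj = np.arange(self.reg_max, dtype=np.float32)

    # -------------------------------------------------------------- decode
    def flatten(self, preds):
        """Raw per-level predictions -> (box_dist (B,A,4,R), cls (B,A,nc),
        anchors (A,2), stride per anchor (A,))."""
        shapes = [b.shape[2:] for b, _ in preds]
        anchors, astr = Detect.make_anchors(shapes, self.strides)
        bparts, cparts = [], []
        for (b, c) in preds:
            n, _, h, w = b.shape
            bparts.append(b.reshape(n, 4 * self.reg_max, h * w))
            cparts.append(c.reshape(n, self.nc, h * w))
        box = Tensor.concat(bparts, axis=2).transpose(0, 2, 1)
        cls = Tensor.concat(cparts, axis=2).transpose(0, 2, 1)
        n = box.shape[0]
        box = box.reshape(n, -1, 4, self.reg_max)
        return box, cls, anchors, astr

    def decode(self, box_dist: Tensor, anchors, astr) -> Tensor:
        """Distribution logits -> corner boxes in pixels (differentiable)."""
        probs = box_dist.softmax(axis=-1)
        ltrb = (probs * self.proj.reshape(1, 1, 1, -1)).sum(axis=-1)
        ltrb = ltrb * astr.reshape(1, -1, 1)
        x1y1 = Tensor(anchors[None]) - ltrb.narrow(2, 0, 2)
        x2y2 = Tensor(anchors[None]) + ltrb.narrow(2, 2, 2)
        return Tensor.concat([x1y1, x2y2], axis=2)

    # ---------------------------------------------------------------- loss
    def __call__(self, preds, targets, training: bool = True):
        """targets: list (length batch) of (cls (Mi,), boxes_xyxy_px (Mi,4)).

        Returns (total, parts dict of floats).
        """
        box_dist, cls_logits, anchors, astr = self.flatten(preds)
        pboxes = self.decode(box_dist, anchors, astr)     # (B,A,4)
        b, a = cls_logits.shape[0], cls_logits.shape[1]
        scores_np = 1.0 / (1.0 + np.exp(-cls_logits.data))
        fg_all = np.zeros((b, a), dtype=bool)
        tscores = np.zeros((b, a, self.nc), dtype=np.float32)
        tboxes = np.zeros((b, a, 4), dtype=np.float32)
        for i, (gcls, gbox) in enumerate(targets):
            fg, gidx, ts = self.assigner(scores_np[i], pboxes.data[i],
                                         anchors, np.asarray(gcls),
                                         np.asarray(gbox, dtype=np.float64))
            fg_all[i] = fg
            tscores[i] = ts
            if fg.any():
                tboxes[i][fg] = np.asarray(gbox, dtype=np.float32)[gidx[fg]]
        ts_sum = max(float(tscores.sum()), 1.0)

        cls_loss = cls_logits.bce_with_logits(tscores).sum() * (1.0 / ts_sum)

        if fg_all.any():
            w = tscores.sum(axis=2)[fg_all].astype(np.float32)
            pred_fg = pboxes[fg_all]                      # (F,4)
            gt_fg = tboxes[fg_all]
            if self.box_variant == "wiou":
                pair_loss, _ = wiou_loss_batch(pred_fg, gt_fg, self.wiou,
                                               training)
            else:
                pair_loss = self._plain_iou_loss(pred_fg, gt_fg)
            box_loss = (pair_loss * Tensor(w)).sum() * (1.0 / ts_sum)
            dfl_loss = self._dfl(box_dist, anchors, astr, tboxes, fg_all,
                                 w) * (1.0 / ts_sum)
        else:
            box_loss = Tensor(0.0)
            dfl_loss = Tensor(0.0)

        bw, cw, dw = self.weights
        total = box_loss * bw + cls_loss * cw + dfl_loss * dw
        parts = {"box": float(box_loss.data), "cls": float(cls_loss.data),
                 "dfl": float(dfl_loss.data), "total": float(total.data)}
        return total, parts

    def _plain_iou_loss(self, pred: Tensor, gt: np.ndarray) -> Tensor:
        gt = np.asarray(gt, dtype=np.float32)
        iw = Tensor.minimum(pred.narrow(1, 2, 1), gt[:, 2:3]) - \
            Tensor.maximum(pred.narrow(1, 0, 1), gt[:, 0:1])
        ih = Tensor.minimum(pred.narrow(1, 3, 1), gt[:, 3:4]) - \
            Tensor.maximum(pred.narrow(1, 1, 1), gt[:, 1:2])
        inter = iw.clamp(0, None) * ih.clamp(0, None)
        ap = (pred.narrow(1, 2, 1) - pred.narrow(1, 0, 1)) * \
            (pred.narrow(1, 3, 1) - pred.narrow(1, 1, 1))
        ag = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
        union = ap + ag.reshape(-1, 1) - inter
        return (1.0 - inter / (union + 1e-9)).reshape(-1)

    def _dfl(self, box_dist: Tensor, anchors, astr, tboxes, fg, w) -> Tensor:
        """Distribution focal loss on the two bins bracketing each target
        edge distance (in stride units)."""
        dist_fg = box_dist[fg]                            # (F,4,R)
        anc = np.broadcast_to(anchors[None], tboxes.shape[:2] + (2,))[fg]
        st = np.broadcast_to(astr[None], tboxes.shape[:2])[fg][:, None]
        gt = tboxes[fg]
        lt = (anc - gt[:, :2]) / st
        rb = (gt[:, 2:] - anc) / st
        target = np.clip(np.concatenate([lt, rb], axis=1), 0,
                         self.reg_max - 1 - 0.01)         # (F,4)
        tl = np.floor(target).astype(np.int64)
        tr = tl + 1
        wl = (tr - target).astype(np.float32)
        wr = 1.0 - wl
        logp = dist_fg.log_softmax(axis=-1)
        f = target.shape[0]
        ii = np.arange(f)[:, None]
        jj = np.arange(4)[None, :]
        ce = -(logp[ii, jj, tl] * Tensor(wl) + logp[ii, jj, tr] * Tensor(wr))
        return (ce.mean(axis=1) * Tensor(np.asarray(w, dtype=np.float32))).sum()
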