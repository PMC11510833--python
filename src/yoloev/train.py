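"""Training loop, inference decoding and dataset evaluation.

Training follows the family recipe at desk scale: SGD with momentum 0.9,
initial learning rate 0.01, seeded shuffling, per-epoch JSONL logging and
best/last checkpoints.  Inference decodes the distributional box head into
corner boxes, applies a confidence threshold and per-class greedy NMS.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, no_grad
from .blocks import Detect
from .boxes import Box, nms, xywhn_to_xyxy
from .data import _resize_nearest, load_dataset_yaml
from .losses import DetectionLoss
from .metrics import DetectionRecord, evaluate_detections, map_range
from .model import DetectionModel, ModelConfig, build_model, \
    load_checkpoint, save_checkpoint
from .nn import SGD

__all__ = ["RunConfig", "Trainer", "predict", "evaluate_model"]


@dataclass
class RunConfig:
    model_yaml: str | None = None
    dataset_yaml: str = "dataset.yaml"
    epochs: int = 300
    batch: int = 16
    lr0: float = 0.01
    momentum: float = 0.9
    optimizer: str = "sgd"
    seed: int = 0
    out_dir: str = "runs/train"
    warmup_steps: int = 10


# ---------------------------------------------------------------- decode
def decode_predictions(preds, strides, reg_max: int = 16):
    """Raw head outputs -> (boxes (B,A,4) px, scores (B,A,nc))."""
    shapes = [b.shape[2:] for b, _ in preds]
    anchors, astr = Detect.make_anchors(shapes, strides)
    boxes, scores = [], []
    for (b, c) in preds:
        n, _, h, w = b.shape
        boxes.append(b.data.reshape(n, 4, reg_max, h * w))
        scores.append(c.data.reshape(n, c.shape[1], h * w))
    dist = np.concatenate(boxes, axis=3)          # (B,4,R,A)
    z = dist - dist.max(axis=2, keepdims=True)
    e = np.exp(z)
    e /= e.sum(axis=2, keepdims=True)
    ltrb = np.einsum("nkra,r->nka", e, np.arange(reg_max, dtype=np.float32))
    ltrb *= astr[None, None, :]
    x1y1 = anchors.T[None] - ltrb[:, :2]
    x2y2 = anchors.T[None] + ltrb[:, 2:]
    out_boxes = np.concatenate([x1y1, x2y2], axis=1).transpose(0, 2, 1)
    out_scores = 1.0 / (1.0 + np.exp(-np.concatenate(scores, axis=2)))
    return out_boxes, out_scores.transpose(0, 2, 1)


def predict(model: DetectionModel, images: np.ndarray, conf_thr: float = 0.25,
            nms_iou: float = 0.6, image_ids=None) -> list:
    """Run the detector on a (B,3,H,W) float batch -> DetectionRecords."""
    model.eval()
    with no_grad():
        preds = model(Tensor(images))
    boxes, scores = decode_predictions(preds, model.cfg.strides,
                                       model.cfg.reg_max)
    records = []
    for i in range(len(images)):
        img_id = image_ids[i] if image_ids else str(i)
        cls_id = scores[i].argmax(axis=1)
        conf = scores[i].max(axis=1)
        keep = conf >= conf_thr
        bx, cf, cl = boxes[i][keep], conf[keep], cls_id[keep]
        for c in np.unique(cl):
            m = cl == c
            kept = nms(bx[m], cf[m], nms_iou)
            for j in kept:
                x1, y1, x2, y2 = bx[m][j]
                if x2 <= x1 or y2 <= y1:
                    continue
                records.append(DetectionRecord(img_id, int(c),
                                               float(cf[m][j]),
                                               Box(*map(float, (x1, y1, x2, y2)))))
    return records


def _prep_batch(items, imgsz: int):
    """Dataset items -> (images (B,3,S,S) float, targets, gt records)."""
    ims, targets, gts = [], [], []
    for img, labels, stem in items:
        if img.shape[0] != imgsz:
            img = _resize_nearest(img, imgsz, imgsz)
        ims.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        if labels:
            cls = np.array([b[0] for b in labels], dtype=np.int64)
            xyxy = xywhn_to_xyxy(np.array([b[1:] for b in labels]),
                                 imgsz, imgsz)
        else:
            cls = np.zeros(0, dtype=np.int64)
            xyxy = np.zeros((0, 4))
        targets.append((cls, xyxy))
        for c, bb in zip(cls, xyxy):
            gts.append(DetectionRecord(stem, int(c), 1.0, Box(*map(float, bb))))
    return np.stack(ims), targets, gts


def evaluate_model(model: DetectionModel, items, imgsz: int | None = None,
                   conf_thr: float = 0.03, nms_iou: float = 0.6) -> dict:
    """P, R, mAP@0.5 and mAP@0.5:0.95 (overall and per class)."""
    imgsz = imgsz or model.cfg.imgsz
    dets, gts = [], []
    for i in range(0, len(items), 8):
        ims, _, g = _prep_batch(items[i:i + 8], imgsz)
        ids = [it[2] for it in items[i:i + 8]]
        dets += predict(model, ims, conf_thr, nms_iou, image_ids=ids)
        gts += g
    if not gts:
        raise ValueError("evaluation set has no ground truths")
    map50, map5095 = map_range(dets, gts)
    res50 = evaluate_detections(dets, gts, 0.5)
    # P/R at the evaluation confidence threshold
    from .metrics import match_detections
    flags = match_detections(dets, gts, 0.5)
    tp = int(flags.sum())
    fp = len(flags) - tp
    fn = len(gts) - tp
    return {"precision": tp / max(tp + fp, 1), "recall": tp / max(tp + fn, 1),
            "map50": map50, "map50_95": map5095,
            "per_class_ap50": res50.per_class,
            "n_detections": len(dets), "n_gts": len(gts)}


class Trainer:
    """Seeded SGD training with JSONL logging and checkpointing."""

    def __init__(self, model: DetectionModel, run: RunConfig):
        self.model = model
        self.run = run
        self.loss_fn = DetectionLoss(model)
        self.opt = SGD(model.parameters(), lr=run.lr0, momentum=run.momentum)
        self.out = Path(run.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.log_path = self.out / "log.jsonl"
        self.start_epoch = 0
        self.step = 0

    def _log(self, record: dict):
        with open(self.log_path, "a") as f:
            f.write(json.dumps(record) + "\n")

    def train_steps(self, items, steps: int, imgsz: int | None = None,
                    log_every: int = 20) -> list:
        """Iterate optimizer steps over shuffled mini-batches; returns the
        per-step total losses."""
        imgsz = imgsz or self.model.cfg.imgsz
        rng = np.random.default_rng(self.run.seed)
        self.model.train()
        losses = []
        order = []
        while True:
            if len(order) < self.run.batch:
                order += list(rng.permutation(len(items)))
            idx, order = order[:self.run.batch], order[self.run.batch:]
            ims, targets, _ = _prep_batch([items[i] for i in idx], imgsz)
            # linear warmup guards the first updates of a fresh model
            warm = min(1.0, (self.step + 1) / max(self.run.warmup_steps, 1))
            self.opt.lr = self.run.lr0 * warm
            self.opt.zero_grad()
            total, parts = self.loss_fn(self.model(Tensor(ims)), targets)
            total.backward()
            self.opt.step()
            losses.append(parts["total"])
            self.step += 1
            if self.step % log_every == 0 or self.step == 1:
                self._log({"step": self.step, **parts})
            if self.step >= steps:
                return losses

    def fit(self, dataset_yaml, epochs: int | None = None,
            imgsz: int | None = None, eval_every: int = 1) -> dict:
        meta, load_split = load_dataset_yaml(dataset_yaml)
        if meta["nc"] != self.model.cfg.nc:
            raise ValueError(
                f"dataset has {meta['nc']} classes but the model expects "
                f"{self.model.cfg.nc}")
        train_items = load_split("train")
        val_items = load_split("val")
        imgsz = imgsz or self.model.cfg.imgsz
        epochs = epochs or self.run.epochs
        steps_per_epoch = max(1, len(train_items) // self.run.batch)
        best_map = -1.0
        history = {"loss": [], "map50": []}
        for epoch in range(self.start_epoch, epochs):
            t0 = time.time()
            losses = self.train_steps(train_items,
                                      self.step + steps_per_epoch, imgsz)
            rec = {"epoch": epoch, "loss": float(np.mean(losses)),
                   "lr": self.opt.lr, "time_s": round(time.time() - t0, 2)}
            if (epoch + 1) % eval_every == 0 and val_items:
                stats = evaluate_model(self.model, val_items, imgsz)
                rec["map50"] = stats["map50"]
                history["map50"].append(stats["map50"])
                if stats["map50"] > best_map:
                    best_map = stats["map50"]
                    save_checkpoint(self.model, self.out / "best.npz",
                                    {"epoch": epoch, "map50": best_map})
            history["loss"].append(rec["loss"])
            self._log(rec)
            save_checkpoint(self.model, self.out / "last.npz",
                            {"epoch": epoch, "step": self.step})
        return history

    @classmethod
    def resume(cls, run: RunConfig) -> "Trainer":
        model, extra = load_checkpoint(Path(run.out_dir) / "last.npz")
        t = cls(model, run)
        t.start_epoch = int(extra.get("epoch", -1)) + 1
        t.step = int(extra.get("step", 0))
        return t
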