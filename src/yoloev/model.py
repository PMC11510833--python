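"""Config-driven assembly of the baseline and extended-vision detectors.

A :class:`ModelConfig` names the compound scale (n/s/m), the three
architecture toggles (MGEFA backbone attention, P6 pyramid level with a C2
neck, LSKA-augmented pooling) and the class count.  ``build_model`` turns it
into a :class:`DetectionModel`:

* backbone: stem + four stages of stride-2 conv + C2f (MGEFAC2f when the
  attention toggle is on), a fifth P6 stage when ``p6`` is set, ending in
  SPPF (or SPPF_LSKA);
* neck: top-down + bottom-up path aggregation over three levels (C2f) or,
  with ``p6``, four levels built from the cheaper C2 blocks;
* head: decoupled anchor-free detection over all levels.

P6 models follow the standard convention of the family: the P5 stage
narrows to base width 768 and the added P6 stage carries base width 1024,
so the pooling block (and the LSKA attention span) sits at the model's
widest point.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .attention import LSKAConfig, MGEFAC2f, MGEFAConfig, SPPFLSKA
from .autograd import Tensor
from .blocks import C2, C2f, ConvBNAct, Detect, SPPF
from .nn import Module, Upsample2x

__all__ = ["ModelConfig", "DetectionModel", "build_model",
           "save_checkpoint", "load_checkpoint"]

# depth multiple, width multiple, width cap
SCALES = {
    "n": (0.33, 0.25, 1024),
    "s": (0.33, 0.50, 1024),
    "m": (0.67, 0.75, 768),
}

CHECKPOINT_VERSION = 1


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(x + divisor / 2) // divisor * divisor)


@dataclass
class ModelConfig:
    scale: str = "s"
    mgefa: bool = False
    p6: bool = False
    lska: bool = False
    nc: int = 20
    imgsz: int = 640
    reg_max: int = 16
    seed: int = 0
    mgefa_cfg: MGEFAConfig = field(default_factory=MGEFAConfig)
    lska_cfg: LSKAConfig = field(default_factory=LSKAConfig)

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; pick one of n/s/m")
        if self.imgsz % self.max_stride:
            raise ValueError(
                f"imgsz={self.imgsz} must be divisible by {self.max_stride}")

    @property
    def depth_mult(self) -> float:
        return SCALES[self.scale][0]

    @property
    def width_mult(self) -> float:
        return SCALES[self.scale][1]

    @property
    def max_channels(self) -> int:
        return SCALES[self.scale][2]

    @property
    def strides(self) -> tuple:
        return (8, 16, 32, 64) if self.p6 else (8, 16, 32)

    @property
    def max_stride(self) -> int:
        return 64 if self.p6 else 32

    def width(self, base: int) -> int:
        return make_divisible(min(base, self.max_channels) * self.width_mult)

    def depth(self, n: int) -> int:
        return max(round(n * self.depth_mult), 1)

    # ------------------------------------------------------------- yaml io
    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("mgefa_cfg", "lska_cfg")}
        d["mgefa_cfg"] = {"branch_specs": [list(b) for b in
                                           self.mgefa_cfg.branch_specs],
                          "lse_pool_grid": self.mgefa_cfg.lse.pool_grid,
                          "lse_channel_kernel": self.mgefa_cfg.lse.channel_kernel}
        d["lska_cfg"] = {"local_k": self.lska_cfg.local_k,
                         "dilated_k": self.lska_cfg.dilated_k,
                         "dilation": self.lska_cfg.dilation}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        mg = d.pop("mgefa_cfg", None)
        ls = d.pop("lska_cfg", None)
        cfg = cls(**d)
        if mg:
            from .attention import LSEConfig
            cfg.mgefa_cfg = MGEFAConfig(
                branch_specs=tuple(tuple(b) for b in mg["branch_specs"]),
                lse=LSEConfig(mg["lse_pool_grid"], mg["lse_channel_kernel"]))
        if ls:
            cfg.lska_cfg = LSKAConfig(**ls)
        return cfg

    def save_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "ModelConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


class DetectionModel(Module):
    """Assembled detector; see module docstring for the topology."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        W, D = cfg.width, cfg.depth
        c1, c2_, c3_, c4 = W(64), W(128), W(256), W(512)
        c5 = W(768) if cfg.p6 else W(1024)
        c6 = W(1024)
        self.ch = {8: c3_, 16: c4, 32: c5, 64: c6}

        def stage(cin, cout, n):
            if cfg.mgefa:
                return MGEFAC2f(cin, cout, n, shortcut=True,
                                cfg=cfg.mgefa_cfg, rng=rng)
            return C2f(cin, cout, n, shortcut=True, rng=rng)

        # ----- backbone
        self.stem1 = ConvBNAct(3, c1, 3, 2, rng=rng)
        self.stem2 = ConvBNAct(c1, c2_, 3, 2, rng=rng)
        self.stage2 = stage(c2_, c2_, D(3))
        self.down3 = ConvBNAct(c2_, c3_, 3, 2, rng=rng)
        self.stage3 = stage(c3_, c3_, D(6))
        self.down4 = ConvBNAct(c3_, c4, 3, 2, rng=rng)
        self.stage4 = stage(c4, c4, D(6))
        self.down5 = ConvBNAct(c4, c5, 3, 2, rng=rng)
        self.stage5 = stage(c5, c5, D(3))
        if cfg.p6:
            self.down6 = ConvBNAct(c5, c6, 3, 2, rng=rng)
            self.stage6 = stage(c6, c6, D(3))
        ctop = c6 if cfg.p6 else c5
        if cfg.lska:
            self.sppf = SPPFLSKA(ctop, ctop, cfg=cfg.lska_cfg, rng=rng)
        else:
            self.sppf = SPPF(ctop, ctop, rng=rng)

        # ----- neck
        self.up = Upsample2x()
        if cfg.p6:
            self.td5 = C2(c6 + c5, c5, D(3), shortcut=False, rng=rng)
            self.td4 = C2(c5 + c4, c4, D(3), shortcut=False, rng=rng)
            self.td3 = C2(c4 + c3_, c3_, D(3), shortcut=False, rng=rng)
            self.bu_conv3 = ConvBNAct(c3_, c3_, 3, 2, rng=rng)
            self.bu4 = C2(c3_ + c4, c4, D(3), shortcut=False, rng=rng)
            self.bu_conv4 = ConvBNAct(c4, c4, 3, 2, rng=rng)
            self.bu5 = C2(c4 + c5, c5, D(3), shortcut=False, rng=rng)
            self.bu_conv5 = ConvBNAct(c5, c5, 3, 2, rng=rng)
            self.bu6 = C2(c5 + c6, c6, D(3), shortcut=False, rng=rng)
            head_ch = [c3_, c4, c5, c6]
        else:
            self.td4 = C2f(c5 + c4, c4, D(3), shortcut=False, rng=rng)
            self.td3 = C2f(c4 + c3_, c3_, D(3), shortcut=False, rng=rng)
            self.bu_conv3 = ConvBNAct(c3_, c3_, 3, 2, rng=rng)
            self.bu4 = C2f(c3_ + c4, c4, D(3), shortcut=False, rng=rng)
            self.bu_conv4 = ConvBNAct(c4, c4, 3, 2, rng=rng)
            self.bu5 = C2f(c4 + c5, c5, D(3), shortcut=False, rng=rng)
            head_ch = [c3_, c4, c5]

        self.detect = Detect(cfg.nc, head_ch, list(cfg.strides),
                             cfg.reg_max, rng=rng)
        self.detect.bias_init()

    # ------------------------------------------------------------ forward
    def backbone(self, x: Tensor):
        x = self.stem2(self.stem1(x))
        x = self.stage2(x)
        p3 = self.stage3(self.down3(x))
        p4 = self.stage4(self.down4(p3))
        p5 = self.stage5(self.down5(p4))
        if self.cfg.p6:
            p6 = self.stage6(self.down6(p5))
            return p3, p4, p5, self.sppf(p6)
        return p3, p4, self.sppf(p5)

    def forward(self, x: Tensor):
        """Per-level (box_logits, cls_logits) raw predictions."""
        if self.cfg.p6:
            p3, p4, p5, top = self.backbone(x)
            t5 = self.td5(Tensor.concat([self.up(top), p5], axis=1))
            t4 = self.td4(Tensor.concat([self.up(t5), p4], axis=1))
            t3 = self.td3(Tensor.concat([self.up(t4), p3], axis=1))
            b4 = self.bu4(Tensor.concat([self.bu_conv3(t3), t4], axis=1))
            b5 = self.bu5(Tensor.concat([self.bu_conv4(b4), t5], axis=1))
            b6 = self.bu6(Tensor.concat([self.bu_conv5(b5), top], axis=1))
            feats = [t3, b4, b5, b6]
        else:
            p3, p4, top = self.backbone(x)
            t4 = self.td4(Tensor.concat([self.up(top), p4], axis=1))
            t3 = self.td3(Tensor.concat([self.up(t4), p3], axis=1))
            b4 = self.bu4(Tensor.concat([self.bu_conv3(t3), t4], axis=1))
            b5 = self.bu5(Tensor.concat([self.bu_conv4(b4), top], axis=1))
            feats = [t3, b4, b5]
        return self.detect(feats)

    # ------------------------------------------------------------- profiling
    def flops(self, imgsz: int | None = None) -> int:
        """Analytic FLOPs for one image (2 per MAC, norm fused)."""
        s = imgsz or self.cfg.imgsz
        g = {k: s // k for k in (2, 4, 8, 16, 32, 64)}
        total = 0
        total += self.stem1.flops(s, s)
        total += self.stem2.flops(g[2], g[2])
        total += self.stage2.flops(g[4], g[4])
        total += self.down3.flops(g[4], g[4]) + self.stage3.flops(g[8], g[8])
        total += self.down4.flops(g[8], g[8]) + self.stage4.flops(g[16], g[16])
        total += self.down5.flops(g[16], g[16]) + self.stage5.flops(g[32], g[32])
        if self.cfg.p6:
            total += self.down6.flops(g[32], g[32])
            total += self.stage6.flops(g[64], g[64])
            gt = g[64]
        else:
            gt = g[32]
        total += self.sppf.flops(gt, gt)
        if self.cfg.p6:
            total += self.td5.flops(g[32], g[32])
            total += self.td4.flops(g[16], g[16])
            total += self.td3.flops(g[8], g[8])
            total += self.bu_conv3.flops(g[8], g[8]) + self.bu4.flops(g[16], g[16])
            total += self.bu_conv4.flops(g[16], g[16]) + self.bu5.flops(g[32], g[32])
            total += self.bu_conv5.flops(g[32], g[32]) + self.bu6.flops(g[64], g[64])
        else:
            total += self.td4.flops(g[16], g[16])
            total += self.td3.flops(g[8], g[8])
            total += self.bu_conv3.flops(g[8], g[8]) + self.bu4.flops(g[16], g[16])
            total += self.bu_conv4.flops(g[16], g[16]) + self.bu5.flops(g[32], g[32])
        for i, st in enumerate(self.cfg.strides):
            total += self.detect.box_convs[i].flops(s // st, s // st)
            total += self.detect.cls_convs[i].flops(s // st, s // st)
        return total


def build_model(cfg: ModelConfig) -> DetectionModel:
    return DetectionModel(cfg)


# ------------------------------------------------------------- checkpoints
def save_checkpoint(model: DetectionModel, path, extra: dict | None = None):
    meta = {"version": CHECKPOINT_VERSION, "config": model.cfg.to_dict(),
            "extra": extra or {}}
    arrays = {k.replace("buffer:", "B@"): v for k, v in
              model.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[DetectionModel, dict]:
    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["__meta__"]))
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    cfg = ModelConfig.from_dict(meta["config"])
    model = build_model(cfg)
    state = {}
    for k in z.files:
        if k == "__meta__":
            continue
        key = k.replace("B@", "buffer:")
        state[key] = z[k]
    model.load_state_dict(state)
    return model, meta["extra"]
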