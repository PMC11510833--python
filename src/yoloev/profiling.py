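"""Structural profiling: exact trainable-parameter counts and analytic FLOPs.

Parameter counts sum the actual parameter arrays of an assembled model (the
fixed DFL projection is a buffer, not a parameter, and is excluded).  FLOPs
follow the reference profiler convention: 2 FLOPs per multiply-accumulate
of every convolution on the norm-fused graph, batch 1.

Printed "(M)" values truncate to one decimal (floor), the convention under
which the family's published tables are reproduced; GFLOPs round to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import DetectionModel, ModelConfig, build_model

__all__ = ["ProfileReport", "count_parameters", "count_flops",
           "profile_model", "profile_grid", "params_m"]


def params_m(params: int) -> float:
    """Millions of parameters, truncated to one decimal."""
    return int(params / 1e5) / 10


def count_parameters(model: DetectionModel) -> int:
    """Exact number of trainable scalars."""
    return model.num_params()


def count_flops(model: DetectionModel, imgsz: int | None = None) -> float:
    """GFLOPs for a single image at ``imgsz`` squared."""
    return model.flops(imgsz) / 1e9


@dataclass
class ProfileReport:
    name: str
    params: int
    params_m: float
    gflops: float
    per_module: dict = field(default_factory=dict)

    def row(self) -> str:
        return f"{self.name:<28s} {self.params:>12,d} {self.params_m:>8.1f} " \
               f"{self.gflops:>8.1f}"

    @staticmethod
    def header() -> str:
        return f"{'model':<28s} {'params':>12s} {'M':>8s} {'GFLOPs':>8s}"


def _variant_name(cfg: ModelConfig) -> str:
    tags = [t for t, on in (("mgefa", cfg.mgefa), ("p6", cfg.p6),
                            ("lska", cfg.lska)) if on]
    base = f"yolov8{cfg.scale}"
    return base + ("-" + "-".join(tags) if tags else "")


def profile_model(cfg: ModelConfig, imgsz: int | None = None) -> ProfileReport:
    model = build_model(cfg)
    p = count_parameters(model)
    per = {name: m.num_params() for name, m in model._modules.items()}
    return ProfileReport(_variant_name(cfg), p, params_m(p),
                         round(count_flops(model, imgsz), 1), per)


def profile_grid(rows, scale: str = "s", nc: int = 20,
                 imgsz: int = 640) -> list[ProfileReport]:
    """One report per (mgefa, p6, lska) toggle combination."""
    out = []
    for mgefa, p6, lska in rows:
        cfg = ModelConfig(scale=scale, mgefa=mgefa, p6=p6, lska=lska,
                          nc=nc, imgsz=imgsz)
        out.append(profile_model(cfg, imgsz))
    return out
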