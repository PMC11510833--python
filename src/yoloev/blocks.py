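"""Building blocks of the YOLOv8-family detector.

ConvBNAct (conv + batch norm + activation), the split-transform-concat
C2f/C2 blocks, fast spatial pyramid pooling (SPPF) and the anchor-free
decoupled detection head with a distributional box regression (DFL).

Channel conventions follow the reference family: C2f/C2 halve the output
width internally, bottlenecks run at full hidden width with two 3x3
convolutions, SPPF halves the width before three cascaded 5x5 max-pools.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import (BatchNorm2d, Conv2d, MaxPool2d, Module, ModuleList,
                 Parameter, Sequential, SiLU, ReLU, Identity)

__all__ = ["ConvBNAct", "Bottleneck", "C2f", "C2", "SPPF", "DFL", "Detect",
           "autopad"]


def autopad(k: int, d: int = 1) -> int:
    return (d * (k - 1)) // 2


_ACTS = {"silu": SiLU, "relu": ReLU, "none": Identity}


class ConvBNAct(Module):
    """Convolution + batch norm + activation; 'same' padding.

    Stride-1 blocks preserve spatial dims exactly; stride-2 blocks emit
    ceil(input/2).  The convolution carries no bias (the norm supplies the
    shift), so trainable parameters are k*k*cin*cout/groups + 2*cout.
    """

    def __init__(self, cin, cout, kernel=1, stride=1, groups=1, dilation=1,
                 act: str = "silu", rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride,
                           padding=autopad(kernel if isinstance(kernel, int)
                                           else max(kernel), dilation),
                           dilation=dilation, groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = _ACTS[act]()
        self.cout = cout

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(Module):
    """Two 3x3 ConvBNAct at full hidden width, optional residual add."""

    def __init__(self, cin, cout, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(cin, cout, 3, rng=rng)
        self.cv2 = ConvBNAct(cout, cout, 3, rng=rng)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Split-transform-concat block that concatenates the untouched split
    half plus every intermediate bottleneck output before a 1x1 fusion."""

    def __init__(self, cin, cout, n=1, shortcut=False, rng=None):
        super().__init__()
        if n < 1:
            raise ValueError(f"C2f needs n >= 1, got {n}")
        self.c = cout // 2
        self.cv1 = ConvBNAct(cin, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNAct((2 + n) * self.c, cout, 1, rng=rng)
        self.m = ModuleList([Bottleneck(self.c, self.c, shortcut, rng=rng)
                             for _ in range(n)])

    def forward(self, x):
        y = list(self.cv1(x).chunk(2, axis=1))
        for b in self.m:
            y.append(b(y[-1]))
        return self.cv2(Tensor.concat(y, axis=1))


class C2(Module):
    """Cheaper sibling of C2f: bottlenecks run sequentially on one split
    half and only the two halves are concatenated before fusion."""

    def __init__(self, cin, cout, n=1, shortcut=True, rng=None):
        super().__init__()
        if n < 1:
            raise ValueError(f"C2 needs n >= 1, got {n}")
        self.c = cout // 2
        self.cv1 = ConvBNAct(cin, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNAct(2 * self.c, cout, 1, rng=rng)
        self.m = Sequential(*[Bottleneck(self.c, self.c, shortcut, rng=rng)
                              for _ in range(n)])

    def forward(self, x):
        a, b = self.cv1(x).chunk(2, axis=1)
        return self.cv2(Tensor.concat([self.m(a), b], axis=1))


class SPPF(Module):
    """Fast spatial pyramid pooling: three cascaded k x k max-pools whose
    concatenation reproduces direct pooling at k, 2k-1 and 3k-2."""

    def __init__(self, cin, cout, pool_k: int = 5, rng=None):
        super().__init__()
        if pool_k % 2 == 0:
            raise ValueError(f"SPPF pool kernel must be odd, got {pool_k}")
        c = cin // 2
        self.cv1 = ConvBNAct(cin, c, 1, rng=rng)
        self.cv2 = ConvBNAct(4 * c, cout, 1, rng=rng)
        self.pool = MaxPool2d(pool_k, 1, pool_k // 2)

    def concat_features(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return Tensor.concat(y, axis=1)

    def forward(self, x):
        return self.cv2(self.concat_features(x))


class DFL(Module):
    """Distribution focal decode: expectation over reg_max softmax bins.

    The projection weights are the fixed bin offsets 0..reg_max-1 and are
    not trainable.
    """

    def __init__(self, reg_max: int = 16):
        super().__init__()
        self.reg_max = reg_max
        self.register_buffer("proj", np.arange(reg_max, dtype=np.float32))

    def forward(self, x: Tensor) -> np.ndarray:
        # x: (n, 4*reg_max, a) logits -> (n, 4, a) expected offsets
        n, _, a = x.shape
        p = x.data.reshape(n, 4, self.reg_max, a)
        p = p - p.max(axis=2, keepdims=True)
        e = np.exp(p)
        e /= e.sum(axis=2, keepdims=True)
        return np.einsum("nkra,r->nka", e, self.proj)


class Detect(Module):
    """Decoupled anchor-free head over an ordered list of pyramid levels.

    Per level, a box branch emits ``4*reg_max`` distribution logits and a
    class branch emits ``nc`` logits.  Branch widths follow the family
    convention: box width max(16, ch0/4, 4*reg_max); class width
    max(ch0, min(nc, 100)).
    """

    def __init__(self, nc: int, ch: list[int], strides: list[int],
                 reg_max: int = 16, rng=None):
        super().__init__()
        if len(set(strides)) != len(strides):
            raise ValueError(f"detection strides must be distinct, got {strides}")
        if list(strides) != sorted(strides):
            raise ValueError(f"features must be ordered by stride, got {strides}")
        self.nc, self.reg_max = nc, reg_max
        self.strides = list(strides)
        self.nl = len(ch)
        c2 = max(16, ch[0] // 4, 4 * reg_max)
        c3 = max(ch[0], min(nc, 100))
        self.box_convs = ModuleList([
            Sequential(ConvBNAct(c, c2, 3, rng=rng),
                       ConvBNAct(c2, c2, 3, rng=rng),
                       Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng))
            for c in ch])
        self.cls_convs = ModuleList([
            Sequential(ConvBNAct(c, c3, 3, rng=rng),
                       ConvBNAct(c3, c3, 3, rng=rng),
                       Conv2d(c3, nc, 1, bias=True, rng=rng))
            for c in ch])
        self.dfl = DFL(reg_max)

    def bias_init(self):
        """Prior-aware initialisation of the final layer biases: box bias 1,
        class bias set for ~5e-3 positive rate scaled by stride area."""
        for i, s in enumerate(self.strides):
            self.box_convs[i][2].bias.data[...] = 1.0
            self.cls_convs[i][2].bias.data[...] = float(
                np.log(5.0 / self.nc / (640.0 / s) ** 2))

    def forward(self, feats: list[Tensor]):
        """Returns per-level (box_logits, cls_logits) pairs."""
        if len(feats) != self.nl:
            raise ValueError(f"expected {self.nl} feature maps, got {len(feats)}")
        return [(self.box_convs[i](f), self.cls_convs[i](f))
                for i, f in enumerate(feats)]

    @staticmethod
    def make_anchors(shapes, strides, offset: float = 0.5):
        """Anchor centre points (in pixels) and per-anchor stride."""
        pts, strs = [], []
        for (h, w), s in zip(shapes, strides):
            xs = (np.arange(w, dtype=np.float32) + offset) * s
            ys = (np.arange(h, dtype=np.float32) + offset) * s
            gx, gy = np.meshgrid(xs, ys)
            pts.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
            strs.append(np.full(h * w, s, dtype=np.float32))
        return np.concatenate(pts), np.concatenate(strs)
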