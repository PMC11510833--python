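"""Attention blocks: LSE, MGEFA, MGEFAC2f, LSKA and SPPF_LSKA.

LSE (localized spatial-channel attention) pools a feature map to a coarse
grid and runs a 1-D convolution *across the channel axis* at each pooled
cell, producing per-cell per-channel sigmoid gates that are broadcast back
over the map.  MGEFA runs parallel grouped/depthwise convolution branches
(batch norm + ReLU), gates each through its own LSE, sums the branches and
adds the input residually — so with zeroed branch weights it is an exact
identity.  LSKA factorises a large depthwise kernel into horizontal and
vertical 1-D depthwise convolutions (a short dense pair plus a long dilated
pair) followed by a pointwise mix, and multiplies the input by the
resulting attention map.  SPPF_LSKA applies LSKA to the 4-way concatenated
hidden map of SPPF before the final fusion convolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .blocks import C2f, ConvBNAct, SPPF
from .nn import Conv2d, Module, ModuleList

__all__ = ["LSEConfig", "MGEFAConfig", "LSKAConfig",
           "LSE", "MGEFA", "MGEFAC2f", "LSKA", "SPPFLSKA"]


@dataclass
class LSEConfig:
    """Pooled-grid edge and channel-kernel span of the LSE gate."""
    pool_grid: int = 4
    channel_kernel: int = 3

    def __post_init__(self):
        if self.pool_grid < 1:
            raise ValueError("pool_grid must be >= 1")
        if self.channel_kernel % 2 == 0:
            raise ValueError("channel_kernel must be odd")


@dataclass
class MGEFAConfig:
    """Branch layout of MGEFA.

    Each branch spec is ``(kernel, group_width)``: ``group_width`` is the
    channel count per convolution group (``None`` means depthwise).  The
    defaults — a pointwise conv with 32-wide groups and a 3x3 depthwise —
    keep the block parameter-light enough that inserting it throughout a
    backbone leaves the 0.1M-rounded model size unchanged.
    """
    branch_specs: tuple = ((1, 32), (3, None))
    lse: LSEConfig = field(default_factory=LSEConfig)
    residual: bool = True


@dataclass
class LSKAConfig:
    """Separable large-kernel attention decomposition.

    ``local_k``-tap dense 1-D pairs plus ``dilated_k``-tap pairs at
    ``dilation`` give an effective receptive field of
    ``local_k + dilation * (dilated_k - 1)`` (55 with the defaults).
    """
    local_k: int = 7
    dilated_k: int = 17
    dilation: int = 3

    def __post_init__(self):
        if self.local_k % 2 == 0 or self.dilated_k % 2 == 0:
            raise ValueError("LSKA kernel taps must be odd")

    @property
    def effective_kernel(self) -> int:
        return self.local_k + self.dilation * (self.dilated_k - 1)


class LSE(Module):
    """Localized spatial-channel attention gate.

    Adaptive-average-pools to ``g x g``, slides a single-channel 1-D
    convolution along the channel axis of each pooled cell, squashes through
    a sigmoid and rescales the input by the (broadcast) gates.  With zeroed
    convolution weights every gate is sigmoid(0) = 0.5.
    """

    def __init__(self, channels: int, cfg: LSEConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or LSEConfig()
        if channels < cfg.channel_kernel:
            raise ValueError(
                f"need at least {cfg.channel_kernel} channels, got {channels}")
        self.cfg = cfg
        self.channels = channels
        # 1 x k kernel sliding over the channel axis
        self.conv1d = Conv2d(1, 1, (1, cfg.channel_kernel), bias=True, rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.cfg.pool_grid
        if g > min(h, w):
            warnings.warn(
                f"LSE pool grid {g} exceeds spatial dims {h}x{w}; clamping")
            g = min(h, w)
        pooled = x.adaptive_avg_pool2d(g)                    # (n, c, g, g)
        seq = pooled.transpose(0, 2, 3, 1).reshape(n * g * g, 1, 1, c)
        att = self.conv1d(seq).sigmoid()
        att = att.reshape(n, g, g, c).transpose(0, 3, 1, 2)  # (n, c, g, g)
        if h % g == 0 and w % g == 0:
            return att.repeat_spatial(h // g, w // g)
        # ragged broadcast: nearest-neighbour via index gather
        hi = (np.arange(h) * g // h)
        wi = (np.arange(w) * g // w)
        return att[:, :, hi[:, None], wi[None, :]]

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gates(x)

    def flops(self, h, w):
        g = min(self.cfg.pool_grid, h, w)
        return 2 * self.cfg.channel_kernel * self.channels * g * g


class MGEFA(Module):
    """Multi-branch group-enhanced fusion attention.

    branch_i = LSE_i(ReLU(BN(conv_i(x)))); output = x + sum_i branch_i.
    Every branch preserves the channel count and spatial dims.
    """

    def __init__(self, channels: int, cfg: MGEFAConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or MGEFAConfig()
        if len(cfg.branch_specs) < 2:
            raise ValueError("MGEFA needs at least two branches")
        self.cfg = cfg
        self.channels = channels
        convs, gates = [], []
        for k, gw in cfg.branch_specs:
            groups = channels if gw is None else max(1, channels // gw)
            convs.append(ConvBNAct(channels, channels, k, groups=groups,
                                   act="relu", rng=rng))
            gates.append(LSE(channels, cfg.lse, rng=rng))
        self.branches = ModuleList(convs)
        self.gates = ModuleList(gates)

    def forward(self, x: Tensor) -> Tensor:
        out = x if self.cfg.residual else None
        for conv, gate in zip(self.branches, self.gates):
            y = gate(conv(x))
            out = y if out is None else out + y
        return out


class MGEFAC2f(Module):
    """C2f followed by MGEFA: cascaded feature fusion, then multi-branch
    attention over the fused map."""

    def __init__(self, cin, cout, n=1, shortcut=False,
                 cfg: MGEFAConfig | None = None, rng=None):
        super().__init__()
        self.c2f = C2f(cin, cout, n, shortcut, rng=rng)
        self.att = MGEFA(cout, cfg, rng=rng)

    def forward(self, x):
        return self.att(self.c2f(x))


class LSKA(Module):
    """Large separable kernel attention.

    attention = 1x1( dw_dilated_v( dw_dilated_h( dw_v( dw_h(x) ) ) ) );
    output = x * attention.  All spatial convolutions are depthwise 1-D
    pairs, so the dense equivalent kernel is the outer product of the
    horizontal and vertical taps.
    """

    def __init__(self, channels: int, cfg: LSKAConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or LSKAConfig()
        self.cfg = cfg
        c, k1, k2, d = channels, cfg.local_k, cfg.dilated_k, cfg.dilation
        self.conv0h = Conv2d(c, c, (1, k1), groups=c, bias=True, rng=rng)
        self.conv0v = Conv2d(c, c, (k1, 1), groups=c, bias=True, rng=rng)
        self.conv_sh = Conv2d(c, c, (1, k2), dilation=d, groups=c, bias=True,
                              rng=rng)
        self.conv_sv = Conv2d(c, c, (k2, 1), dilation=d, groups=c, bias=True,
                              rng=rng)
        self.conv1 = Conv2d(c, c, 1, bias=True, rng=rng)

    def attention(self, x: Tensor) -> Tensor:
        a = self.conv0v(self.conv0h(x))
        a = self.conv_sv(self.conv_sh(a))
        return self.conv1(a)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention(x)

    def set_identity(self):
        """Configure to an exact identity gate of 1 (for testing/ablation):
        depthwise kernels become centred deltas, the mix becomes identity
        with a +1 bias offset cancelled by zero input path."""
        for conv in (self.conv0h, self.conv0v, self.conv_sh, self.conv_sv):
            conv.weight.data[...] = 0.0
            conv.weight.data[..., conv.kh // 2, conv.kw // 2] = 1.0
            conv.bias.data[...] = 0.0
        self.conv1.weight.data[...] = 0.0
        self.conv1.bias.data[...] = 1.0


class SPPFLSKA(Module):
    """SPPF with LSKA applied to the 4-way concatenated hidden map before
    the final 1x1 fusion."""

    def __init__(self, cin, cout, pool_k: int = 5,
                 cfg: LSKAConfig | None = None, rng=None):
        super().__init__()
        self.sppf = SPPF(cin, cout, pool_k, rng=rng)
        self.lska = LSKA(4 * (cin // 2), cfg, rng=rng)

    def forward(self, x):
        y = self.sppf.concat_features(x)
        return self.sppf.cv2(self.lska(y))
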