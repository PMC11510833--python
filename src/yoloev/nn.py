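"""Neural-network layer abstractions over the autograd core.

Mirrors the familiar ``Module``/``Parameter`` organisation: modules own
parameters and submodules, expose ``parameters()`` / ``state_dict()`` and a
``train()``/``eval()`` mode switch.  Layers implement ``forward`` on
:class:`~yoloev.autograd.Tensor` inputs and, where meaningful, an analytic
``flops(h, w)`` used by the profiler (2 FLOPs per multiply-accumulate on the
norm-fused graph).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Parameter(Tensor):
    """A tensor registered as trainable state of a module."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    # ------------------------------------------------------------ traversal
    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def state_dict(self):
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d):
        for n, p in self.named_parameters():
            p.data[...] = d[n]
        for n, b in self.named_buffers():
            key = "buffer:" + n
            if key in d:
                b[...] = d[key]

    def num_params(self) -> int:
        """Exact count of trainable scalars."""
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def flops(self, h: int, w: int) -> int:  # overridden by leaves/blocks
        return sum(m.flops(h, w) for m in self._modules.values())


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._seq = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._seq.append(m)

    def __iter__(self):
        return iter(self._seq)

    def __len__(self):
        return len(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, f"m{len(self._list)}", m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Bare convolution (optionally biased); padding is 'same' for the
    declared kernel/dilation unless given explicitly."""

    def __init__(self, cin, cout, kernel=1, stride=1, padding=None,
                 dilation=1, groups=1, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError(
                f"groups={groups} must divide both in={cin} and out={cout}")
        kh, kw = kernel if isinstance(kernel, tuple) else (kernel, kernel)
        if padding is None:
            padding = ((dilation * (kh - 1)) // 2, (dilation * (kw - 1)) // 2)
        self.cin, self.cout = cin, cout
        self.kh, self.kw = kh, kw
        self.stride, self.padding, self.dilation, self.groups = \
            stride, padding, dilation, groups
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * kh * kw
        self.weight = Parameter(_kaiming(rng, (cout, cin // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]} channels, "
                f"layer expects {self.cin}")
        return x.conv2d(self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)

    def flops(self, h: int, w: int) -> int:
        # non-square 'same' padding: output dims follow stride only
        ho = (h + self.stride - 1) // self.stride
        wo = (w + self.stride - 1) // self.stride
        return 2 * self.kh * self.kw * self.cin * self.cout // self.groups * ho * wo


class BatchNorm2d(Module):
    def __init__(self, c, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.batch_norm(self.weight, self.bias, self.running_mean,
                            self.running_var, self.training,
                            self.momentum, self.eps)

    def flops(self, h, w):
        return 0  # fused into the preceding convolution


class SiLU(Module):
    def forward(self, x):
        return x.silu()

    def flops(self, h, w):
        return 0


class ReLU(Module):
    def forward(self, x):
        return x.relu()

    def flops(self, h, w):
        return 0


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.kernel, self.stride, self.pad = kernel, stride, padding

    def forward(self, x):
        return x.max_pool2d(self.kernel, self.stride, self.pad)

    def flops(self, h, w):
        return 0


class Upsample2x(Module):
    def forward(self, x):
        return x.upsample_nearest2x()

    def flops(self, h, w):
        return 0


class SGD:
    """Stochastic gradient descent with classical momentum and optional
    weight decay (decay applied to conv/linear weights only, by convention
    left to the caller via parameter groups)."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
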