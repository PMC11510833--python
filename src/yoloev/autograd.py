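"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's compute core: a :class:`Tensor` wrapping a ``float32`` ndarray
with a gradient slot and a backward closure.  Only the operations the
detector family needs are implemented (elementwise arithmetic and
activations, matmul, reshaping, concatenation, indexing, reductions, 2-D
convolution with stride/dilation/groups, max/average pooling, nearest
upsampling, batch normalisation, softmax and binary cross-entropy).

Convolution runs through an im2col lowering (``sliding_window_view`` plus a
single matmul / einsum); its backward scatters gradients back with one
vectorised slice-add per kernel tap, which keeps the pure-Python overhead at
a handful of array operations per layer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 1000  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free closure + grads of interior nodes to bound memory
                node._backward = None
                node._parents = ()

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        o = self._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.shape))

        return self._make(self.data + o.data, (self, o), back)

    __radd__ = __add__

    def __mul__(self, other):
        o = self._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.shape))

        return self._make(self.data * o.data, (self, o), back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        o = self._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data ** 2), o.shape))

        return self._make(self.data / o.data, (self, o), back)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def back(g):
            self._accum(_unbroadcast(g * p * self.data ** (p - 1), self.shape))

        return self._make(self.data ** p, (self,), back)

    # --------------------------------------------------------- activations
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), back)

    def log(self):
        def back(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), back)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def back(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return self._make(out_data, (self,), back)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), back)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            self._accum(g * (s + self.data * s * (1.0 - s)))

        return self._make(self.data * s, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), back)

    def clamp(self, lo=None, hi=None):
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def back(g):
            self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), back)

    # ----------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def back(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def back(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), back)

    def __getitem__(self, idx):
        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), back)

    @staticmethod
    def concat(tensors, axis: int = 0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
        if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._parents = tuple(tensors)
            out._backward = back
        return out

    def chunk(self, n: int, axis: int = 1):
        size = self.shape[axis] // n
        return [self.narrow(axis, i * size, size) for i in range(n)]

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        sl = [slice(None)] * self.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def back(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            self._accum(full)

        return self._make(self.data[sl], (self,), back)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        idx = self.data.argmax(axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def back(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full)

        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        return self._make(out_data, (self,), back)

    @staticmethod
    def maximum(a, b) -> "Tensor":
        a, b = Tensor._wrap(a), Tensor._wrap(b)
        mask = a.data >= b.data

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * mask, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ~mask, b.shape))

        return a._make(np.maximum(a.data, b.data), (a, b), back)

    @staticmethod
    def minimum(a, b) -> "Tensor":
        a, b = Tensor._wrap(a), Tensor._wrap(b)
        mask = a.data <= b.data

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * mask, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * ~mask, b.shape))

        return a._make(np.minimum(a.data, b.data), (a, b), back)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        soft = np.exp(out)

        def back(g):
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return self._make(out, (self,), back)

    # --------------------------------------------------------------- linalg
    def matmul(self, other: "Tensor") -> "Tensor":
        o = self._wrap(other)

        def back(g):
            if self.requires_grad:
                self._accum(g @ o.data.swapaxes(-1, -2))
            if o.requires_grad:
                o._accum(self.data.swapaxes(-1, -2) @ g)

        return self._make(self.data @ o.data, (self, o), back)

    __matmul__ = matmul

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return self._make(s, (self,), back)

    def bce_with_logits(self, target: np.ndarray) -> "Tensor":
        """Elementwise binary cross-entropy on logits (numerically stable)."""
        x = self.data
        t = np.asarray(target, dtype=np.float32)
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

        def back(g):
            self._accum(g * (1.0 / (1.0 + np.exp(-x)) - t))

        return self._make(loss, (self,), back)

    # -------------------------------------------------------- spatial ops
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, dilation: int = 1,
               groups: int = 1) -> "Tensor":
        """2-D cross-correlation, NCHW layout, OIHW weights."""
        x, w = self.data, weight.data
        n, cin, h, wd = x.shape
        cout, cin_g, kh, kw = w.shape
        if cin != cin_g * groups:
            raise ValueError(
                f"conv2d channel mismatch: input has {cin} channels, "
                f"weight expects {cin_g * groups} (groups={groups})")
        s, d = stride, dilation
        ph, pw = padding if isinstance(padding, tuple) else (padding, padding)
        if ph or pw:
            xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        else:
            xp = x
        eh, ew = d * (kh - 1) + 1, d * (kw - 1) + 1  # effective kernel extent
        ho = (xp.shape[2] - eh) // s + 1
        wo = (xp.shape[3] - ew) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
        win = win[:, :, ::s, ::s, ::d, ::d]  # (n, cin, ho, wo, kh, kw)

        if groups == 1:
            col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                n * ho * wo, cin * kh * kw)
            wmat = w.reshape(cout, cin * kh * kw)
            out = (col @ wmat.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
        else:
            wing = win.reshape(n, groups, cin_g, ho, wo, kh, kw)
            wg = w.reshape(groups, cout // groups, cin_g, kh, kw)
            out = np.einsum("ngchwuv,gocuv->ngohw", wing, wg, optimize=True)
            out = out.reshape(n, cout, ho, wo)
        out = np.ascontiguousarray(out)
        if bias is not None:
            out += bias.data.reshape(1, cout, 1, 1)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def back(g):
            g = np.ascontiguousarray(g)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                if groups == 1:
                    gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
                    colw = np.ascontiguousarray(
                        win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                            n * ho * wo, cin * kh * kw)
                    weight._accum((gm.T @ colw).reshape(w.shape))
                else:
                    wing = win.reshape(n, groups, cin_g, ho, wo, kh, kw)
                    gg = g.reshape(n, groups, cout // groups, ho, wo)
                    dw = np.einsum("ngohw,ngchwuv->gocuv", gg, wing, optimize=True)
                    weight._accum(dw.reshape(w.shape))
            if self.requires_grad:
                if groups == 1:
                    gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
                    dcol = (gm @ w.reshape(cout, -1)).reshape(
                        n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                else:
                    gg = g.reshape(n, groups, cout // groups, ho, wo)
                    wg = w.reshape(groups, cout // groups, cin_g, kh, kw)
                    dcol = np.einsum("ngohw,gocuv->ngchwuv", gg, wg,
                                     optimize=True).reshape(
                        n, cin, ho, wo, kh, kw)
                dxp = np.zeros_like(xp)
                for u in range(kh):
                    hu = u * d
                    for v in range(kw):
                        wv = v * d
                        dxp[:, :, hu:hu + s * ho:s, wv:wv + s * wo:s] += \
                            dcol[:, :, :, :, u, v]
                self._accum(dxp[:, :, ph:ph + h, pw:pw + wd]
                            if (ph or pw) else dxp)

        return self._make(out, parents, back)

    def max_pool2d(self, kernel: int, stride: int = 1, padding: int = 0) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        s, p, k = stride, padding, kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def back(g):
            dxp = np.zeros_like(xp)
            u, v = np.unravel_index(idx, (k, k))
            ii = u + s * np.arange(ho)[None, None, :, None]
            jj = v + s * np.arange(wo)[None, None, None, :]
            nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
            np.add.at(dxp, (nn[:, :, None, None], cc[:, :, None, None], ii, jj), g)
            self._accum(dxp[:, :, p:p + h, p:p + w] if p else dxp)

        return self._make(np.ascontiguousarray(out), (self,), back)

    def adaptive_avg_pool2d(self, out_hw: int) -> "Tensor":
        """Average-pool to an ``out_hw x out_hw`` grid with torch bin edges."""
        x = self.data
        n, c, h, w = x.shape
        g = out_hw
        hs = [(int(np.floor(i * h / g)), int(np.ceil((i + 1) * h / g))) for i in range(g)]
        ws = [(int(np.floor(j * w / g)), int(np.ceil((j + 1) * w / g))) for j in range(g)]
        out = np.empty((n, c, g, g), dtype=np.float32)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                out[:, :, i, j] = x[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

        def back(gr):
            dx = np.zeros_like(x)
            for i, (h0, h1) in enumerate(hs):
                for j, (w0, w1) in enumerate(ws):
                    area = (h1 - h0) * (w1 - w0)
                    dx[:, :, h0:h1, w0:w1] += gr[:, :, i:i + 1, j:j + 1] / area
            self._accum(dx)

        return self._make(out, (self,), back)

    def upsample_nearest2x(self) -> "Tensor":
        def back(g):
            n, c, h2, w2 = g.shape
            self._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

        return self._make(self.data.repeat(2, axis=2).repeat(2, axis=3),
                          (self,), back)

    def repeat_spatial(self, fh: int, fw: int) -> "Tensor":
        """Nearest-neighbour repeat by integer factors on H and W."""
        def back(g):
            n, c, h2, w2 = g.shape
            self._accum(
                g.reshape(n, c, h2 // fh, fh, w2 // fw, fw).sum(axis=(3, 5)))

        return self._make(self.data.repeat(fh, axis=2).repeat(fw, axis=3),
                          (self,), back)

    def batch_norm(self, weight: "Tensor", bias: "Tensor",
                   running_mean: np.ndarray, running_var: np.ndarray,
                   training: bool, momentum: float = 0.03,
                   eps: float = 1e-3) -> "Tensor":
        """Per-channel batch normalisation over an NCHW tensor.

        Running statistics are updated in place when ``training`` is true.
        """
        x = self.data
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            running_mean *= (1 - momentum)
            running_mean += momentum * mu
            running_var *= (1 - momentum)
            running_var += momentum * var * (m / max(m - 1, 1))
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        out = xhat * weight.data.reshape(1, -1, 1, 1) + bias.data.reshape(1, -1, 1, 1)

        def back(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                weight._accum((g * xhat).sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gw = g * weight.data.reshape(1, -1, 1, 1)
                if training:
                    m = x.shape[0] * x.shape[2] * x.shape[3]
                    sum_g = gw.sum(axis=(0, 2, 3), keepdims=True)
                    sum_gx = (gw * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    dx = (gw - sum_g / m - xhat * sum_gx / m) * \
                        inv.reshape(1, -1, 1, 1)
                else:
                    dx = gw * inv.reshape(1, -1, 1, 1)
                self._accum(dx.astype(np.float32))

        return self._make(out.astype(np.float32), (self, weight, bias), back)
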