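"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the reconstruction framework needs:
dense N-D convolutions, pointwise nonlinearities, pooling/upsampling,
concatenation, reductions, and a bridge between complex-valued images
and 2-channel real tensors.  Complex tensors carry the gradient
convention ``grad = dL/dRe + i * dL/dIm`` (L real), under which the
vector-Jacobian product of any C-linear operator is its conjugate
transpose — which is what makes backprop through FFTs, warps and
conjugate-gradient solves a matter of applying adjoints.

Custom linear operators plug in through :func:`linear_op`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "linear_op", "custom_op"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self.grad = None
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros(self.data.shape, dtype=g.dtype)
        self.grad = self.grad + g

    def zero_grad(self):
        self.grad = None

    # ---- graph construction helpers -------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other))
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data, _prev=(self, other))

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * np.conj(other.data) if np.iscomplexobj(self.data) else g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * np.conj(self.data) if np.iscomplexobj(other.data) else g * self.data, other.data.shape))

            out._backward = bw
            return out
        c = other
        out = Tensor(self.data * c, _prev=(self,))

        def bw_s(g):
            if self.requires_grad:
                self._accum(g * np.conj(c) if np.iscomplexobj(self.data) else g * c)

        out._backward = bw_s
        return out

    __rmul__ = __mul__
    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(np.real(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- pointwise -------------------------------------------------------

    def leaky_relu(self, alpha: float = 0.1):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, alpha * self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.where(mask, g, alpha * g))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - y**2))
        return out

    def square(self):
        out = Tensor(self.data**2, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(2.0 * g * self.data)
        return out

    def sqrt(self, eps: float = 0.0):
        y = np.sqrt(self.data + eps)
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * 0.5 / np.maximum(y, 1e-30))
        return out

    def mean(self):
        out = Tensor(np.array(self.data.mean()), _prev=(self,))
        n = self.data.size
        out._backward = lambda g: self.requires_grad and self._accum(np.broadcast_to(g / n, self.data.shape).copy())
        return out

    def sum(self):
        out = Tensor(np.array(self.data.sum()), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.broadcast_to(g, self.data.shape).copy())
        return out

    def item(self) -> float:
        return float(np.real(self.data).reshape(-1)[0]) if self.data.size == 1 else float(self.data)

    # ---- shape ops -------------------------------------------------------

    def unsqueeze(self, axis: int = 0):
        out = Tensor(np.expand_dims(self.data, axis), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.squeeze(g, axis=axis))
        return out

    def crop(self, slices):
        out = Tensor(self.data[slices], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros(self.data.shape, dtype=g.dtype)
                full[slices] = g
                self._accum(full)

        out._backward = bw
        return out

    def pad(self, pad_width):
        out = Tensor(np.pad(self.data, pad_width), _prev=(self,))
        sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pad_width, self.data.shape))
        out._backward = lambda g: self.requires_grad and self._accum(g[sl])
        return out

    # ---- complex bridge --------------------------------------------------

    def to_channels(self):
        """complex (*S) -> real (2, *S)."""
        out = Tensor(np.stack([self.data.real, self.data.imag]), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g[0] + 1j * g[1])
        return out

    def to_complex(self):
        """real (2, *S) -> complex (*S)."""
        out = Tensor(self.data[0] + 1j * self.data[1], _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.stack([g.real, g.imag]))
        return out

    def magnitude(self, eps: float = 1e-9):
        """complex -> real |z| (smoothed at the origin)."""
        m = np.sqrt(np.abs(self.data) ** 2 + eps**2)
        out = Tensor(m, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * self.data / m)
        return out


def _unbroadcast(g, shape):
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def concat(tensors, axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, o, n in zip(tensors, offs, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o, o + n)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def add_n(tensors) -> Tensor:
    data = sum(t.data for t in tensors)
    out = Tensor(data, _prev=tuple(tensors))

    def bw(g):
        for t in tensors:
            if t.requires_grad:
                t._accum(g)

    out._backward = bw
    return out


def linear_op(x: Tensor, fwd, adj) -> Tensor:
    """Apply a (C-)linear operator with a known adjoint.

    ``fwd`` and ``adj`` act on raw arrays; the VJP of a C-linear map
    under the gradient convention used here is exactly ``adj``.
    """
    out = Tensor(fwd(x.data), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(adj(g))
    return out


def custom_op(inputs, out_data, vjp) -> Tensor:
    """General custom node: ``vjp(g)`` returns one gradient per input."""
    out = Tensor(out_data, _prev=tuple(inputs))

    def bw(g):
        grads = vjp(g)
        for t, gr in zip(inputs, grads):
            if t.requires_grad and gr is not None:
                t._accum(gr)

    out._backward = bw
    return out


# ---- dense N-D convolution ----------------------------------------------


def conv(x: Tensor, kernel: Tensor, bias: Tensor | None = None) -> Tensor:
    """'Same' zero-padded cross-correlation, channels first.

    ``x``: (C_in, *S); ``kernel``: (C_out, C_in, *K) with odd K;
    ``bias``: (C_out,) or None.  Returns (C_out, *S).
    """
    xd, kd = x.data, kernel.data
    nd = xd.ndim - 1
    ks = kd.shape[2:]
    pad = [(k // 2, k // 2) for k in ks]
    xp = np.pad(xd, [(0, 0)] + pad)
    out_data = _conv_forward(xp, kd, xd.shape[1:])
    if bias is not None:
        out_data = out_data + bias.data.reshape((-1,) + (1,) * nd)

    prev = (x, kernel) if bias is None else (x, kernel, bias)
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        gx, gk = _conv_backward(xp, kd, g, xd.shape[1:])
        if x.requires_grad:
            sl = tuple([slice(None)] + [slice(p[0], p[0] + n) for p, n in zip(pad, xd.shape[1:])])
            x._accum(gx[sl])
        if kernel.requires_grad:
            kernel._accum(gk)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=tuple(range(1, g.ndim))))

    out._backward = bw
    return out


def _offsets(ks):
    from itertools import product

    return list(product(*[range(k) for k in ks]))


def _conv_forward(xp, kd, out_spatial):
    c_out, c_in = kd.shape[:2]
    ks = kd.shape[2:]
    out = np.zeros((c_out,) + tuple(out_spatial), dtype=np.result_type(xp, kd))
    for off in _offsets(ks):
        sl = tuple(slice(o, o + n) for o, n in zip(off, out_spatial))
        win = xp[(slice(None),) + sl]  # (C_in, *S)
        w = kd[(slice(None), slice(None)) + off]  # (C_out, C_in)
        out += np.tensordot(w, win, axes=(1, 0))
    return out


def _conv_backward(xp, kd, g, out_spatial):
    c_out, c_in = kd.shape[:2]
    ks = kd.shape[2:]
    gx = np.zeros_like(xp, dtype=g.dtype)
    gk = np.zeros_like(kd, dtype=g.dtype)
    for off in _offsets(ks):
        sl = (slice(None),) + tuple(slice(o, o + n) for o, n in zip(off, out_spatial))
        win = xp[sl]
        w = kd[(slice(None), slice(None)) + off]
        gk[(slice(None), slice(None)) + off] = np.tensordot(g, win, axes=(list(range(1, g.ndim)), list(range(1, win.ndim))))
        gx[sl] += np.tensordot(w, g, axes=(0, 0))
    return gx, gk


def avg_pool(x: Tensor, factor: int = 2) -> Tensor:
    """Average pooling by ``factor`` over all spatial axes (channels first)."""
    xd = x.data
    nd = xd.ndim - 1
    sp = xd.shape[1:]
    if any(n % factor for n in sp):
        raise ValueError(f"spatial dims {sp} not divisible by pool factor {factor}")
    newshape = (xd.shape[0],) + tuple(v for n in sp for v in (n // factor, factor))
    pooled = xd.reshape(newshape).mean(axis=tuple(range(2, 2 * nd + 1, 2)))
    out = Tensor(pooled, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            ge = g / (factor**nd)
            for ax in range(1, nd + 1):
                ge = np.repeat(ge, factor, axis=ax)
            x._accum(ge)

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    xd = x.data
    nd = xd.ndim - 1
    up = xd
    for ax in range(1, nd + 1):
        up = np.repeat(up, factor, axis=ax)
    out = Tensor(up, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            sp = xd.shape[1:]
            newshape = (xd.shape[0],) + tuple(v for n in sp for v in (n, factor))
            x._accum(g.reshape(newshape).sum(axis=tuple(range(2, 2 * nd + 1, 2))))

    out._backward = bw
    return out
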