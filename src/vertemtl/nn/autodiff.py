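"""Minimal reverse-mode automatic differentiation on numpy arrays.

Everything downstream (detection head, dual-decoder segmentation U-Net,
gated-attention classifier, fusion head) is built from the ops defined here.
Tensors are float32 NCHW unless stated otherwise; backward walks a
topologically sorted tape.
"""
from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.float32


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily change the dtype new Tensors are stored in.

    float32 is the training default; float64 is useful when checking the
    ops against high-precision references.
    """
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph ----------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    # convenience reductions
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = g.astype(t.data.dtype, copy=False)
    t.grad = g if t.grad is None else t.grad + g


# -- arithmetic ---------------------------------------------------------------
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, p) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        _accum(a, g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        _accum(a, g * 0.5 / np.maximum(data, 1e-12))

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - data * data))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * data * (1.0 - data))

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        _accum(a, g * (a.data > 0))

    return _make(data, (a,), backward)


def clip(a, lo, hi) -> Tensor:
    """Hard clamp; gradient is zero outside [lo, hi]."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)

    def backward(g):
        _accum(a, g * ((a.data >= lo) & (a.data <= hi)))

    return _make(data, (a,), backward)


# -- shape ops ----------------------------------------------------------------
def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(orig))

    return _make(data, (a,), backward)


def concat(tensors, axis=1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


# -- convolution and friends --------------------------------------------------
def _padded(data, p):
    if p == 0:
        return data
    n, c, h, w = data.shape
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=data.dtype)
    out[:, :, p : p + h, p : p + w] = data
    return out


def conv2d(x, w, b=None, stride=1, padding=0) -> Tensor:
    """2-D cross-correlation, NCHW; w is (O, C, k, k).

    Computed as k*k shift-and-matmul passes, which keeps peak memory at one
    feature map instead of an im2col buffer k*k times larger.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    n, c, h, wd = x.data.shape
    o, _, k, _ = w.data.shape
    s, p = stride, padding
    ho = (h + 2 * p - k) // s + 1
    wo = (wd + 2 * p - k) // s + 1
    xp = _padded(x.data, p)
    acc = np.zeros((n, ho, wo, o), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
            # (n, ho, wo, c) @ (c, o)
            acc += np.tensordot(patch, w.data[:, :, i, j], axes=([1], [1]))
    out = np.ascontiguousarray(np.moveaxis(acc, 3, 1))
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gl = np.moveaxis(g, 1, 3)  # (n, ho, wo, o)
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    patch = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
                    # (o, c) = sum over n,ho,wo
                    gw[:, :, i, j] = np.tensordot(gl, patch,
                                                  axes=([0, 1, 2], [0, 2, 3]))
            _accum(w, gw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    # (n, ho, wo, c) from (n, ho, wo, o) @ (o, c)
                    dpatch = np.tensordot(gl, w.data[:, :, i, j], axes=([3], [0]))
                    dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += \
                        np.moveaxis(dpatch, 3, 1)
            _accum(x, dxp[:, :, p : p + h, p : p + wd] if p else dxp)

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out, parents, backward)


def max_pool2d(x, k: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    xr = x.data[:, :, : ho * k, : wo * k].reshape(n, c, ho, k, wo, k)
    out = xr.max(axis=(3, 5))

    def backward(g):
        mask = xr == out[:, :, :, None, :, None]
        cnt = mask.sum(axis=(3, 5), keepdims=True)
        gx = (mask * (g[:, :, :, None, :, None] / cnt)).reshape(n, c, ho * k, wo * k)
        if (ho * k, wo * k) != (h, w):
            gx = np.pad(gx, ((0, 0), (0, 0), (0, h - ho * k), (0, w - wo * k)))
        _accum(x, gx)

    return _make(out, (x,), backward)


def avg_pool2d(x, k: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    ho, wo = h // k, w // k
    xr = x.data[:, :, : ho * k, : wo * k].reshape(n, c, ho, k, wo, k)
    out = xr.mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        if (ho * k, wo * k) != (h, w):
            gx = np.pad(gx, ((0, 0), (0, 0), (0, h - ho * k), (0, w - wo * k)))
        _accum(x, gx)

    return _make(out, (x,), backward)


def upsample_nearest(x, k: int = 2) -> Tensor:
    x = as_tensor(x)
    data = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)

    def backward(g):
        n, c, h, w = x.data.shape
        _accum(x, g.reshape(n, c, h, k, w, k).sum(axis=(3, 5)))

    return _make(data, (x,), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W). Running stats are plain
    numpy arrays mutated in place during training."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None, None]
            if training:
                t1 = dxhat.sum(axis=axes, keepdims=True)
                t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                gx = (dxhat - t1 / m - xhat * t2 / m) * inv_std[None, :, None, None]
            else:
                gx = dxhat * inv_std[None, :, None, None]
            _accum(x, gx)

    return _make(out, (x, gamma, beta), backward)


def softmax(x, axis=-1) -> Tensor:
    x = as_tensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x, axis=-1) -> Tensor:
    x = as_tensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - log(exp(shifted).sum(axis=axis, keepdims=True))
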