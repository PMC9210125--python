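"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every operation returns a :class:`Tensor` that
records its parents and a closure computing vector-Jacobian products.
``Tensor.backward()`` runs the closures in reverse topological order.

Only the operations needed by the super-resolution networks are provided
(elementwise arithmetic, reductions, 2-D convolution and transposed
convolution, bilinear upsampling, batch normalisation, dense layers and the
pointwise nonlinearities). Arrays keep whatever float dtype they are given,
so gradient checks can run in float64 while training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "add",
    "sub",
    "mul",
    "neg",
    "square",
    "tsum",
    "tmean",
    "relu",
    "leaky_relu",
    "sigmoid",
    "log",
    "clamp",
    "reshape",
    "concat",
    "linear",
    "conv2d",
    "conv_transpose2d",
    "bilinear_upsample",
    "batchnorm2d",
]


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                if node.grad is not None:
                    node._backward(node.grad)
                # free closures (cached columns) and intermediate grads eagerly
                node._backward = None
                node._parents = ()
                if not node.requires_grad:
                    node.grad = None

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward, requires: bool) -> Tensor:
    out = Tensor(data, requires_grad=False)
    if requires:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _needs(*ts) -> bool:
    if not _GRAD_ENABLED[0]:
        return False
    return any(isinstance(t, Tensor) and (t.requires_grad or t._backward is not None)
               for t in ts)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    need = _needs(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward, need)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    need = _needs(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), backward, need)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    need = _needs(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward, need)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward, _needs(a))


def square(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, 2.0 * a.data * g)

    return _make(a.data * a.data, (a,), backward, _needs(a))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward, _needs(a))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    scale = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)

    def backward(g):
        _accum(a, g * scale)

    return _make(a.data * scale, (a,), backward, _needs(a))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward, _needs(a))


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward, _needs(a))


def clamp(a, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes through only where no clipping occurred."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        _accum(a, g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), backward, _needs(a))


# -- reductions / shape ---------------------------------------------------

def tsum(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, np.broadcast_to(g, a.shape).copy())

    return _make(a.data.sum(), (a,), backward, _needs(a))


def tmean(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size

    def backward(g):
        _accum(a, np.broadcast_to(g / n, a.shape).copy())

    return _make(a.data.mean(), (a,), backward, _needs(a))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape

    def backward(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward, _needs(a))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward, _needs(*tensors))


# -- dense ----------------------------------------------------------------

def linear(x, w, b=None) -> Tensor:
    """``x @ w.T + b`` for x of shape (N, F) and w of shape (O, F)."""
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def backward(g):
        _accum(x, g @ w.data)
        _accum(w, g.T @ x.data)
        if b is not None:
            _accum(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward, _needs(*parents))


# -- 2-D convolution ------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, oh, ow); cols has shape (C*k*k, N*oh*ow).

    Filled one kernel offset at a time with plain strided slice copies,
    which is far cheaper than reshaping a 6-D sliding-window view.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((c, k, k, n, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            sl = x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            cols[:, i, j] = sl.transpose(1, 0, 2, 3)
    return cols.reshape(c * k * k, n * oh * ow), oh, ow


def _col2im(gcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add column gradients (C*k*k, N*oh*ow) back to input layout."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    g6 = gcols.reshape(c, k, k, n, oh, ow)
    for i in range(k):
        for j in range(k):
            gx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                g6[:, i, j].transpose(1, 0, 2, 3)
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation of (N,C,H,W) with weights (O,C,k,k)."""
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    n = x.shape[0]
    o, c, k, _ = w.shape
    cols, oh, ow = _im2col(x.data, k, stride, pad)
    wmat = w.data.reshape(o, c * k * k)
    out = wmat @ cols                              # (O, N*oh*ow)
    out = out.reshape(o, n, oh, ow).transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, -1)
        _accum(w, (gmat @ cols.T).reshape(w.shape))
        if b is not None:
            _accum(b, gmat.sum(axis=1))
        gcols = wmat.T @ gmat
        _accum(x, _col2im(gcols, x.shape, k, stride, pad))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward, _needs(*parents))


def conv_transpose2d(x, w, b=None, stride: int = 1, pad: int = 0,
                     output_padding: int = 0) -> Tensor:
    """Transposed convolution; weights shaped (C_in, C_out, k, k).

    Output side = (in − 1)·stride − 2·pad + k + output_padding.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    n, c, h, wd = x.shape
    _, o, k, _ = w.shape
    s, p, op = stride, pad, output_padding
    out_h = (h - 1) * s - 2 * p + k + op
    out_w = (wd - 1) * s - 2 * p + k + op
    buf_h = (h - 1) * s + k + op
    buf_w = (wd - 1) * s + k + op

    xmat = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, c)
    wmat = w.data.reshape(c, o * k * k)
    cols = (xmat @ wmat).reshape(n, h, wd, o, k, k).transpose(0, 3, 4, 5, 1, 2)
    buf = np.zeros((n, o, buf_h, buf_w), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            buf[:, :, i:i + s * h:s, j:j + s * wd:s] += cols[:, :, i, j]
    out = buf[:, :, p:p + out_h, p:p + out_w]
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    def backward(g):
        gbuf = np.zeros((n, o, buf_h, buf_w), dtype=g.dtype)
        gbuf[:, :, p:p + out_h, p:p + out_w] = g
        gcols = np.empty((n, o, k, k, h, wd), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gcols[:, :, i, j] = gbuf[:, :, i:i + s * h:s, j:j + s * wd:s]
        gmat = np.ascontiguousarray(
            gcols.transpose(0, 4, 5, 1, 2, 3)).reshape(-1, o * k * k)
        _accum(x, (gmat @ wmat.T).reshape(n, h, wd, c).transpose(0, 3, 1, 2))
        _accum(w, (xmat.T @ gmat).reshape(w.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward, _needs(*parents))


# -- bilinear upsampling --------------------------------------------------

def _interp_matrix(out_n: int, in_n: int, dtype) -> np.ndarray:
    """Linear-interpolation weights, pixel-centre (align-corners-false) grid."""
    m = np.zeros((out_n, in_n), dtype=dtype)
    f = out_n / in_n
    for i in range(out_n):
        src = (i + 0.5) / f - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        m[i, min(max(i0, 0), in_n - 1)] += 1.0 - t
        m[i, min(max(i0 + 1, 0), in_n - 1)] += t
    return m


def bilinear_upsample(x, factor: int) -> Tensor:
    """Upsample (N,C,H,W) by an integer factor with bilinear interpolation."""
    x = as_tensor(x)
    _, _, h, w = x.shape
    mh = _interp_matrix(h * factor, h, x.data.dtype)
    mw = _interp_matrix(w * factor, w, x.data.dtype)
    out = mh @ x.data @ mw.T

    def backward(g):
        _accum(x, mh.T @ g @ mw)

    return _make(out, (x,), backward, _needs(x))


# -- batch normalisation --------------------------------------------------

def batchnorm2d(x, gamma, beta, eps: float = 1e-5):
    """Per-channel batch normalisation over (N, H, W); returns (out, mean, var)."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    mean = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    gshape = gamma.data.reshape(1, -1, 1, 1)
    out = gshape * xhat + beta.data.reshape(1, -1, 1, 1)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        gxhat = g * gshape
        # standard batch-norm backward (biased variance)
        gx = (inv / m) * (m * gxhat
                          - gxhat.sum(axis=axes, keepdims=True)
                          - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True))
        _accum(x, gx)

    t = _make(out, (x, gamma, beta), backward, _needs(x, gamma, beta))
    return t, mean.squeeze(), var.squeeze()
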