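"""Minimal reverse-mode automatic differentiation on numpy arrays.

Float64 throughout so finite-difference gradient checks hold to ~1e-6.
A :class:`Tensor` records its parents and a backward closure; ``backward()``
runs a topological sweep accumulating gradients into ``.grad``.

ReLU supports *guided backpropagation*: inside the :func:`guided_backprop`
context, the backward pass through every ReLU additionally zeroes positions
where the incoming gradient is negative, so only positive contributory paths
survive — the rule used for saliency visualisation.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable

import numpy as np

_GUIDED_MODE = [False]


@contextmanager
def guided_backprop():
    """Context manager enabling the guided rule in ReLU backward passes."""
    _GUIDED_MODE[0] = True
    try:
        yield
    finally:
        _GUIDED_MODE[0] = False


def guided_mode_active() -> bool:
    return _GUIDED_MODE[0]


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, seed: np.ndarray | None = None):
        """Accumulate gradients of this (scalar or seeded) tensor w.r.t.
        every reachable requires_grad tensor."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, exponent):
        return pow_const(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def pow_const(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** exponent

    def backward(g):
        if exponent == 0:
            _accumulate(a, np.zeros_like(a.data))
        else:
            # guard 0**(p-1) at p<1: derivative defined one-sidedly as 0
            with np.errstate(divide="ignore", invalid="ignore"):
                d = exponent * a.data ** (exponent - 1)
            d = np.where(np.isfinite(d), d, 0.0)
            _accumulate(a, _unbroadcast(g * d, a.data.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * out_data)

    return Tensor(out_data, parents=(a,), backward=backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        _accumulate(a, g / a.data)

    return Tensor(out_data, parents=(a,), backward=backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        gated = g * mask
        if _GUIDED_MODE[0]:
            gated = np.where(g > 0, gated, 0.0)
        _accumulate(a, gated)

    return Tensor(out_data, parents=(a,), backward=backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=backward)


def clip_min(a, minimum: float) -> Tensor:
    """max(a, minimum); gradient passes through where a > minimum."""
    a = as_tensor(a)
    mask = a.data > minimum
    out_data = np.where(mask, a.data, minimum)

    def backward(g):
        _accumulate(a, g * mask)

    return Tensor(out_data, parents=(a,), backward=backward)


# -- shape / reduction --------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        _accumulate(a, g.reshape(orig))

    return Tensor(out_data, parents=(a,), backward=backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accumulate(a, g.transpose(inv))

    return Tensor(out_data, parents=(a,), backward=backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g2 = g
        if axis is not None and not keepdims:
            g2 = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g2, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(a, axis: int, keepdims: bool = False) -> Tensor:
    """Max over one axis; gradient flows to the (first) argmax position."""
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = a.data == out_data
    # route gradient only to the first maximal entry along the axis
    first = np.cumsum(mask, axis=axis) == 1
    mask = mask & first
    res = out_data if keepdims else np.squeeze(out_data, axis=axis)

    def backward(g):
        g2 = g if keepdims else np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g2, a.data.shape) * mask)

    return Tensor(res, parents=(a,), backward=backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return Tensor(out_data, parents=tuple(ts), backward=backward)


# -- linear algebra -----------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


# -- softmax family -----------------------------------------------------

def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - logsumexp
    softmax = np.exp(out_data)

    def backward(g):
        _accumulate(a, g - softmax * g.sum(axis=axis, keepdims=True))

    return Tensor(out_data, parents=(a,), backward=backward)


def gather_rows(a, indices: np.ndarray) -> Tensor:
    """Select one column per row: ``out[i] = a[i, indices[i]]``."""
    a = as_tensor(a)
    idx = np.asarray(indices, dtype=np.int64)
    rows = np.arange(a.data.shape[0])
    out_data = a.data[rows, idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, (rows, idx), g)
        _accumulate(a, full)

    return Tensor(out_data, parents=(a,), backward=backward)


# -- convolution / pooling (NCHW) ---------------------------------------

def _sliding_windows(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View of shape (N, C, Ho, Wo, kh, kw) over a padded NCHW array."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw), writeable=False)


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``weight`` has shape (C_out, C_in, kh, kw); ``bias`` shape (C_out,).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    b = as_tensor(bias) if bias is not None else None
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _sliding_windows(xp, kh, kw, stride)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        _accumulate(weight, (gm.T @ cols).reshape(weight.data.shape))
        if b is not None:
            _accumulate(b, gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wmat).reshape(n, ho, wo, cin, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho * stride:stride,
                        j:j + wo * stride:stride] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            _accumulate(x, dxp)

    return Tensor(out_data, parents=tuple(t for t in (x, weight, b) if t is not None),
                  backward=backward)


def max_pool2d(x, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or kernel
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = _sliding_windows(xp, kernel, kernel, stride)
    n, c, ho, wo = win.shape[:4]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        ii = np.arange(ho)[None, None, :, None] * stride + ki
        jj = np.arange(wo)[None, None, None, :] * stride + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        _accumulate(x, dxp)

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool2d(x) -> Tensor:
    """(N, C, H, W) -> (N, C) channel means (the SE 'squeeze')."""
    return tmean(x, axis=(2, 3))


def global_max_pool2d(x) -> Tensor:
    """(N, C, H, W) -> (N, C) channel maxima."""
    return tmax(tmax(x, axis=3), axis=2)
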