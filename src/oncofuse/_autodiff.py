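"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerics layer under every trainable component of the package
(modality encoders, attention fusion, the domain discriminator).  It keeps a
deliberately small surface: dense float64 tensors, the handful of primitives
the architectures need, and a tape-based ``backward``.  All arithmetic follows
numpy broadcasting; gradients are summed back down to each operand's shape.

Design constraints:

* float64 everywhere, for deterministic, bit-reproducible training runs;
* no in-place mutation of node data after creation (the tape assumes it);
* ``softmax``/``log_softmax``/``logsumexp`` subtract a detached per-row max,
  which leaves gradients unchanged but keeps ``exp`` in range.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special as _special

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "concat",
    "conv2d",
    "cross_entropy",
    "dropout",
    "log_softmax",
    "logsumexp",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcasting introduced or stretched."""
    grad = np.asarray(grad, dtype=np.float64)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this node through the recorded tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)

        # iterative post-order topological sort
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # method forms used by the layers
    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tensor_max(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes or None)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def relu(self):
        return relu(self)

    def tanh(self):
        return tanh(self)

    def sigmoid(self):
        return sigmoid(self)

    def gelu(self):
        return gelu(self)

    def abs(self):
        return absolute(self)

    def sqrt(self):
        return power(self, 0.5)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        g = _unbroadcast(g, t.data.shape)
        t.grad = g if t.grad is None else t.grad + g


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- primitives ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g)
        _accum(b, g)

    return _node(a.data + b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _node(a.data * b.data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data ** 2))

    return _node(a.data / b.data, (a, b), bw)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    p = float(exponent)

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _node(a.data ** p, (a,), bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, g @ np.swapaxes(b.data, -1, -2))
        _accum(b, np.swapaxes(a.data, -1, -2) @ g)

    return _node(a.data @ b.data, (a, b), bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def bw(g):
        _accum(a, g * out_data)

    return _node(out_data, (a,), bw)


def log(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, g / a.data)

    return _node(np.log(a.data), (a,), bw)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def bw(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _node(out_data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = _special.expit(a.data)

    def bw(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return _node(a.data * mask, (a,), bw)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = as_tensor(a)
    cdf = 0.5 * (1.0 + _special.erf(a.data / _SQRT2))

    def bw(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data ** 2)
        _accum(a, g * (cdf + a.data * pdf))

    return _node(a.data * cdf, (a,), bw)


def absolute(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, g * np.sign(a.data))

    return _node(np.abs(a.data), (a,), bw)


def _expand_axes(g: np.ndarray, axis, keepdims: bool) -> np.ndarray:
    if keepdims or axis is None:
        return g
    axes = (axis,) if np.isscalar(axis) else tuple(axis)
    for ax in sorted(a % (g.ndim + len(axes)) for a in axes):
        g = np.expand_dims(g, ax)
    return g


def tensor_sum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        gg = _expand_axes(np.asarray(g), axis, keepdims)
        _accum(a, np.broadcast_to(gg, a.data.shape))

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def tensor_mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in ((axis,) if np.isscalar(axis) else axis)]
    )
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tensor_max(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
    result = out_data if keepdims or axis is None else np.squeeze(out_data, axis=axis)
    if axis is None and not keepdims:
        result = a.data.max()

    def bw(g):
        gg = _expand_axes(np.asarray(g), axis, keepdims)
        _accum(a, mask * gg)

    return _node(result, (a,), bw)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old_shape = a.data.shape

    def bw(g):
        _accum(a, np.asarray(g).reshape(old_shape))

    return _node(a.data.reshape(shape), (a,), bw)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inverse = tuple(np.argsort(axes))

    def bw(g):
        _accum(a, np.transpose(np.asarray(g), inverse))

    return _node(np.transpose(a.data, axes), (a,), bw)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        if a.requires_grad:
            gx = np.zeros_like(a.data)
            np.add.at(gx, idx, g)
            _accum(a, gx)

    return _node(a.data[idx], (a,), bw)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(np.asarray(g), splits, axis=axis)):
            _accum(t, piece)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


# -- composites ------------------------------------------------------------

def softmax(a, axis=-1) -> Tensor:
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # detached
    e = exp(add(a, mul(shift, -1.0)))
    return div(e, tensor_sum(e, axis=axis, keepdims=True))


def logsumexp(a, axis=-1, keepdims=False) -> Tensor:
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # detached
    s = log(tensor_sum(exp(add(a, mul(shift, -1.0))), axis=axis, keepdims=True))
    out = add(s, shift)
    if not keepdims:
        out = reshape(out, np.sum(out.data, axis=axis, keepdims=False).shape)
    return out


def log_softmax(a, axis=-1) -> Tensor:
    a = as_tensor(a)
    return add(a, mul(logsumexp(a, axis=axis, keepdims=True), -1.0))


def cross_entropy(logits, labels) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    labels = np.asarray(labels, dtype=np.int64)
    ls = log_softmax(logits, axis=-1)
    picked = getitem(ls, (np.arange(labels.shape[0]), labels))
    return mul(tensor_mean(picked), -1.0)


def dropout(a, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero with probability ``rate``, rescale the rest."""
    if rate <= 0.0:
        return as_tensor(a)
    if rate >= 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    mask = (rng.random(as_tensor(a).shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


def grad_reverse(a, scale: float = 1.0) -> Tensor:
    """Identity in the forward pass; negated (scaled) gradient in the backward.

    The gradient-reversal trick used for one-step adversarial domain
    alignment: layers upstream of this op receive ``-scale`` times the
    gradient that layers downstream produce.
    """
    a = as_tensor(a)

    def bw(g):
        _accum(a, -float(scale) * np.asarray(g))

    return _node(a.data, (a,), bw)


def conv2d(x, w, b, stride: int = 1) -> Tensor:
    """Valid 2-D convolution via im2col.

    ``x``: (N, H, W, C_in); ``w``: (C_in, kh, kw, C_out); ``b``: (C_out,).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    xd, wd = x.data, w.data
    n, h, wid, cin = xd.shape
    _, kh, kw, cout = wd.shape
    s = int(stride)
    if kh > h or kw > wid:
        raise ValueError(f"kernel ({kh},{kw}) larger than input ({h},{wid})")
    # (N, H-kh+1, W-kw+1, C_in, kh, kw) -> strided subsample
    windows = sliding_window_view(xd, (kh, kw), axis=(1, 2))[:, ::s, ::s]
    ho, wo = windows.shape[1], windows.shape[2]
    feat = cin * kh * kw
    cols = np.ascontiguousarray(windows).reshape(n, ho, wo, feat)
    wm = wd.reshape(feat, cout)
    out_data = cols @ wm + b.data

    def bw(g):
        g = np.asarray(g)
        _accum(b, g.sum(axis=(0, 1, 2)))
        _accum(w, (cols.reshape(-1, feat).T @ g.reshape(-1, cout)).reshape(wd.shape))
        if x.requires_grad:
            gcols = (g @ wm.T).reshape(n, ho, wo, cin, kh, kw)
            gx = np.zeros_like(xd)
            for i in range(kh):
                hi = i + (ho - 1) * s + 1
                for j in range(kw):
                    wj = j + (wo - 1) * s + 1
                    gx[:, i:hi:s, j:wj:s, :] += gcols[:, :, :, :, i, j]
            _accum(x, gx)

    return _node(out_data, (x, w, b), bw)
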