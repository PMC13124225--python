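"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is a define-by-run tape: every operation returns a new
:class:`Tensor` holding a closure that propagates gradients to its parents.
Only the operations needed by the vision-transformer blocks are provided
(dense/batched matmul, 2-D convolutions, attention-style softmax, layer
normalization, GELU/sigmoid, pooling, gather, slicing).  Arrays are kept in
whatever float dtype they arrive in; model parameters are float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

_GRAD_ENABLED = True

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference / oracle computations)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- operators ------------------------------------------------------------
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

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)


def ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = ensure_tensor(a), ensure_tensor(b)
    data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = ensure_tensor(a), ensure_tensor(b)
    data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(grad * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(grad * a.data, b.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = ensure_tensor(a), ensure_tensor(b)
    data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def reshape(t: Tensor, shape) -> Tensor:
    t = ensure_tensor(t)
    data = t.data.reshape(shape)

    def backward(grad):
        t._accumulate(grad.reshape(t.shape))

    return _make(data, (t,), backward)


def transpose(t: Tensor, axes) -> Tensor:
    t = ensure_tensor(t)
    axes = tuple(axes)
    data = t.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(grad):
        t._accumulate(grad.transpose(inv))

    return _make(data, (t,), backward)


def narrow(t: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice `length` entries starting at `start` along `axis`."""
    t = ensure_tensor(t)
    index = [slice(None)] * t.ndim
    index[axis] = slice(start, start + length)
    index = tuple(index)
    data = t.data[index]

    def backward(grad):
        full = np.zeros_like(t.data)
        full[index] = grad
        t._accumulate(full)

    return _make(data, (t,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [ensure_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]

    def backward(grad):
        pieces = np.split(grad, np.cumsum(sizes)[:-1], axis=axis)
        for t, g in zip(ts, pieces):
            if t.requires_grad:
                t._accumulate(g)

    return _make(data, ts, backward)


def repeat_batch(t: Tensor, reps: int) -> Tensor:
    """Repeat each item along axis 0 `reps` times (backward sums the copies)."""
    t = ensure_tensor(t)
    data = np.repeat(t.data, reps, axis=0)

    def backward(grad):
        t._accumulate(grad.reshape((t.shape[0], reps) + t.shape[1:]).sum(axis=1))

    return _make(data, (t,), backward)


def mean(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    t = ensure_tensor(t)
    data = t.data.mean(axis=axis, keepdims=keepdims)
    count = t.data.size if axis is None else np.prod(
        [t.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def backward(grad):
        g = np.asarray(grad)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        t._accumulate(np.broadcast_to(g, t.shape) / count)

    return _make(data, (t,), backward)


def sum_(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    t = ensure_tensor(t)
    data = t.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = np.asarray(grad)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        t._accumulate(np.broadcast_to(g, t.shape).astype(t.data.dtype))

    return _make(data, (t,), backward)


# ---------------------------------------------------------------------------
# nonlinearities and normalization
# ---------------------------------------------------------------------------

def gelu(t: Tensor) -> Tensor:
    t = ensure_tensor(t)
    x = t.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    data = x * cdf

    def backward(grad):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        t._accumulate(grad * (cdf + x * pdf))

    return _make(data, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    t = ensure_tensor(t)
    s = 1.0 / (1.0 + np.exp(-t.data))

    def backward(grad):
        t._accumulate(grad * s * (1.0 - s))

    return _make(s, (t,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    t = ensure_tensor(t)
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(grad):
        dot = (grad * y).sum(axis=axis, keepdims=True)
        t._accumulate(y * (grad - dot))

    return _make(y, (t,), backward)


def layer_norm(t: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    t, weight, bias = ensure_tensor(t), ensure_tensor(weight), ensure_tensor(bias)
    x = t.data
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    data = xhat * weight.data + bias.data

    def backward(grad):
        if weight.requires_grad:
            axes = tuple(range(grad.ndim - 1))
            weight._accumulate((grad * xhat).sum(axis=axes))
        if bias.requires_grad:
            axes = tuple(range(grad.ndim - 1))
            bias._accumulate(grad.sum(axis=axes))
        if t.requires_grad:
            gx = grad * weight.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            t._accumulate((gx - m1 - xhat * m2) * inv)

    return _make(data, (t, weight, bias), backward)


# ---------------------------------------------------------------------------
# convolutions and pooling (NHWC layout)
# ---------------------------------------------------------------------------

def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil division
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """Return (padded x, strided window view (B, Ho, Wo, C, kh, kw))."""
    ph = _same_pad(x.shape[1], kh, stride)
    pw = _same_pad(x.shape[2], kw, stride)
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
    view = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    view = view[:, ::stride, ::stride]
    return xp.shape, view, (ph, pw)


def conv2d(t: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1) -> Tensor:
    """Same-padded 2-D convolution; `weight` has shape (kh, kw, Cin, Cout)."""
    t, weight = ensure_tensor(t), ensure_tensor(weight)
    kh, kw, cin, cout = weight.shape
    if t.shape[-1] != cin:
        raise ValueError(f"conv2d: input has {t.shape[-1]} channels, weight expects {cin}")
    if kh == 1 and kw == 1 and stride == 1:
        return _conv1x1(t, weight, bias)
    pshape, view, _ = _im2col(t.data, kh, kw, stride)
    data = np.tensordot(view, weight.data, axes=([4, 5, 3], [0, 1, 2]))
    parents = [t, weight]
    if bias is not None:
        bias = ensure_tensor(bias)
        data = data + bias.data
        parents.append(bias)
    b_, ho, wo, _ = data.shape

    def backward(grad):
        if bias is not None and bias.requires_grad:
            bias._accumulate(grad.sum(axis=(0, 1, 2)))
        if weight.requires_grad:
            # remaining view axes after contraction: (C, kh, kw) vs grad (Cout)
            gw = np.tensordot(view, grad, axes=([0, 1, 2], [0, 1, 2]))
            weight._accumulate(gw.transpose(1, 2, 0, 3))
        if t.requires_grad:
            dxp = np.zeros(pshape, dtype=t.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    # grad wrt the (i, j) tap: (B, Ho, Wo, Cin)
                    g = grad @ weight.data[i, j].T
                    dxp[:, i : i + (ho - 1) * stride + 1 : stride,
                        j : j + (wo - 1) * stride + 1 : stride, :] += g
            ph = _same_pad(t.shape[1], kh, stride)
            pw = _same_pad(t.shape[2], kw, stride)
            t._accumulate(dxp[:, ph[0] : pshape[1] - ph[1], pw[0] : pshape[2] - pw[1], :])

    return _make(data, parents, backward)


def _conv1x1(t: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Pointwise convolution as a channel matmul (fast path)."""
    w2d = weight.data.reshape(weight.shape[2], weight.shape[3])
    data = t.data @ w2d
    parents = [t, weight]
    if bias is not None:
        bias = ensure_tensor(bias)
        data += bias.data
        parents.append(bias)

    def backward(grad):
        if bias is not None and bias.requires_grad:
            bias._accumulate(grad.sum(axis=(0, 1, 2)))
        if weight.requires_grad:
            gw = np.tensordot(t.data, grad, axes=([0, 1, 2], [0, 1, 2]))
            weight._accumulate(gw.reshape(weight.shape))
        if t.requires_grad:
            t._accumulate(grad @ w2d.T)

    return _make(data, parents, backward)


def depthwise_conv2d(t: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Per-channel same-padded convolution; `weight` has shape (kh, kw, C)."""
    t, weight = ensure_tensor(t), ensure_tensor(weight)
    kh, kw, c = weight.shape
    if t.shape[-1] != c:
        raise ValueError(f"depthwise_conv2d: {t.shape[-1]} channels vs weight {c}")
    b_, h, w_, _ = t.shape
    ph = _same_pad(h, kh, 1)
    pw = _same_pad(w_, kw, 1)
    xp = np.pad(t.data, ((0, 0), ph, pw, (0, 0)))
    data = np.zeros_like(t.data)
    for i in range(kh):
        for j in range(kw):
            data += xp[:, i : i + h, j : j + w_, :] * weight.data[i, j]
    parents = [t, weight]
    if bias is not None:
        bias = ensure_tensor(bias)
        data += bias.data
        parents.append(bias)

    def backward(grad):
        if bias is not None and bias.requires_grad:
            bias._accumulate(grad.sum(axis=(0, 1, 2)))
        if weight.requires_grad:
            gw = np.empty((kh, kw, c), dtype=weight.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gw[i, j] = np.einsum(
                        "bhwc,bhwc->c", xp[:, i : i + h, j : j + w_, :], grad, optimize=True
                    )
            weight._accumulate(gw)
        if t.requires_grad:
            dxp = np.zeros(xp.shape, dtype=t.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + h, j : j + w_, :] += grad * weight.data[i, j]
            t._accumulate(dxp[:, ph[0] : xp.shape[1] - ph[1], pw[0] : xp.shape[2] - pw[1], :])

    return _make(data, parents, backward)


def max_pool_2x2(t: Tensor) -> Tensor:
    t = ensure_tensor(t)
    b, h, w, c = t.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool_2x2 requires even sides, got {h}x{w}")
    blocks = t.data.reshape(b, h // 2, 2, w // 2, 2, c)
    data = blocks.max(axis=(2, 4))

    def backward(grad):
        mask = blocks == data[:, :, None, :, None, :]
        # split gradient equally across ties so the op stays conservative
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (grad[:, :, None, :, None, :] / counts)
        t._accumulate(g.reshape(b, h, w, c))

    return _make(data, (t,), backward)


# ---------------------------------------------------------------------------
# lookup, dropout, loss
# ---------------------------------------------------------------------------

def gather_rows(table: Tensor, index: np.ndarray) -> Tensor:
    """table[index] with scatter-add backward (embedding-style lookup)."""
    table = ensure_tensor(table)
    index = np.asarray(index)
    data = table.data[index]

    def backward(grad):
        g = np.zeros_like(table.data)
        np.add.at(g, index, grad)
        table._accumulate(g)

    return _make(data, (table,), backward)


def dropout(t: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return t
    mask = (rng.random(t.shape) >= p).astype(t.data.dtype) / (1.0 - p)
    return mul(t, Tensor(mask))


def drop_path(t: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Stochastic depth: zero a residual branch per sample with probability p."""
    if not training or p <= 0.0:
        return t
    shape = (t.shape[0],) + (1,) * (t.ndim - 1)
    mask = (rng.random(shape) >= p).astype(t.data.dtype) / (1.0 - p)
    return mul(t, Tensor(mask))


def cross_entropy_with_logits(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Mean over the batch of w_y * (-log softmax(logits)_y)."""
    logits = ensure_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {n}")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"label outside class range 0..{k - 1}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    nll = lse - z[np.arange(n), labels]
    w = np.ones(n, dtype=z.dtype) if class_weights is None else np.asarray(class_weights)[labels]
    data = np.asarray((w * nll).mean())

    def backward(grad):
        p = np.exp(z - lse[:, None])
        p[np.arange(n), labels] -= 1.0
        logits._accumulate(p * (w * float(grad) / n)[:, None])

    return _make(data, (logits,), backward)
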