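"""Minimal tape-based reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the transformer and flow layers in this package:
broadcasting elementwise arithmetic, batched matmul, reductions, the usual
nonlinearities, a numerically stable log-softmax, embedding lookup and a
log|det| primitive for invertible linear layers. Gradients are validated
against finite differences in the test suite.

All computation is float64. A :func:`no_grad` context disables graph
construction for inference.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "dropout_mode",
    "maybe_dropout",
    "concatenate",
    "embedding",
    "log_softmax",
    "softmax",
    "slogdet_abs",
    "erf",
]

_GRAD_ENABLED = [True]
_DROPOUT: list[tuple[float, "np.random.Generator"] | None] = [None]


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


@contextmanager
def dropout_mode(p: float, rng: np.random.Generator):
    """Enable inverted dropout at rate ``p`` inside the context (training)."""
    _DROPOUT.append((p, rng) if p > 0 else None)
    try:
        yield
    finally:
        _DROPOUT.pop()


def maybe_dropout(x: "Tensor") -> "Tensor":
    """Apply dropout when a :func:`dropout_mode` context is active."""
    state = _DROPOUT[-1]
    if state is None:
        return x
    p, rng = state
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * keep


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple["Tensor", ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def _accum_owned(self, grad: np.ndarray) -> None:
        """Accumulate a gradient array the caller guarantees is freshly
        allocated and unshared (skips the defensive copy)."""
        if self.grad is None:
            self.grad = grad
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- op construction ---------------------------------------------------
    @staticmethod
    def _result(
        data: np.ndarray,
        parents: Sequence["Tensor"],
        backward: Callable[[np.ndarray], None],
    ) -> "Tensor":
        req_parents = tuple(p for p in parents if p.requires_grad)
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and req_parents:
            out.requires_grad = True
            out._parents = req_parents
            out._backward = backward
        return out

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum_owned(-g)

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum_owned(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum_owned(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum_owned(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum_owned(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._result(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            a._accum_owned(g * e * a.data ** (e - 1))

        return Tensor._result(a.data**e, (a,), bw)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum_owned(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum_owned(_unbroadcast(gb, b.shape))

        return Tensor._result(a.data @ b.data, (a, b), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            a._accum(g.reshape(old))

        return Tensor._result(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes: tuple[int, ...]):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return Tensor._result(a.data.transpose(axes), (a,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def bw(g):
            a._accum(g.swapaxes(ax1, ax2))

        return Tensor._result(a.data.swapaxes(ax1, ax2), (a,), bw)

    def __getitem__(self, key):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum_owned(full)

        return Tensor._result(a.data[key], (a,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum_owned(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum_owned(np.broadcast_to(gg, a.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out = a.data.max(axis=axis, keepdims=True)
        mask = a.data == out
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum_owned(mask * gg)

        res = out if keepdims else out.squeeze(axis)
        return Tensor._result(res, (a,), bw)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum_owned(g * out_data)

        return Tensor._result(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum_owned(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum_owned(g * (1.0 - out_data**2))

        return Tensor._result(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def bw(g):
            a._accum_owned(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), bw)

    def softplus(self):
        a = self

        def bw(g):
            a._accum_owned(g / (1.0 + np.exp(-np.clip(a.data, -60, 60))))

        return Tensor._result(np.logaddexp(0.0, a.data), (a,), bw)

    def gelu(self):
        from scipy.special import erf as _erf

        a = self
        x = a.data
        cdf = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))

        def bw(g):
            pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
            a._accum_owned(g * (cdf + x * pdf))

        return Tensor._result(x * cdf, (a,), bw)


# -- free functions --------------------------------------------------------

def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    w = weight

    def bw(g):
        full = np.zeros_like(w.data)
        np.add.at(full, idx, g)
        w._accum_owned(full)

    return Tensor._result(w.data[idx], (w,), bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = x
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    sm = np.exp(out_data)

    def bw(g):
        a._accum_owned(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._result(out_data, (a,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def layernorm(x: Tensor, gain: Tensor, shift: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    a, gamma, beta = x, gain, shift
    mu = a.data.mean(axis=-1, keepdims=True)
    centered = a.data - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = centered * inv
    out_data = y * gamma.data + beta.data

    def bw(g):
        if gamma.requires_grad:
            gamma._accum_owned(
                (g * y).sum(axis=tuple(range(g.ndim - 1)))
            )
        if beta.requires_grad:
            beta._accum_owned(g.sum(axis=tuple(range(g.ndim - 1))))
        if a.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * y).mean(axis=-1, keepdims=True)
            a._accum_owned(inv * (gy - m1 - y * m2))

    return Tensor._result(out_data, (a, gamma, beta), bw)


def slogdet_abs(w: Tensor) -> Tensor:
    """log|det W| for a square matrix, with gradient (W^-T)."""
    a = w
    sign, logdet = np.linalg.slogdet(a.data)
    if sign == 0:
        raise np.linalg.LinAlgError("singular matrix in slogdet_abs")

    def bw(g):
        a._accum(float(g) * np.linalg.inv(a.data).T)

    return Tensor._result(np.array(logdet), (a,), bw)


def erf(x: Tensor) -> Tensor:
    from scipy.special import erf as _erf

    a = x

    def bw(g):
        a._accum(g * 2.0 / np.sqrt(np.pi) * np.exp(-a.data**2))

    return Tensor._result(_erf(a.data), (a,), bw)
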