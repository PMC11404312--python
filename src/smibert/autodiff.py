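"""A compact vectorized reverse-mode automatic differentiation engine.

:class:`Tensor` wraps a ``numpy`` array and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``. Only the primitives the Transformer encoder needs are
provided: broadcasting arithmetic, batched ``matmul``, ``exp``/``log``/
``erf``/``tanh``, reductions, reshaping, indexing (with scatter-add
backward), embedding lookup, a numerically stable masked ``softmax`` and
``log_softmax``, layer normalization, GELU and dropout.

Gradients are exact (analytic); tests cross-check them against central
finite differences.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "Adam",
    "clip_gradients",
    "matmul",
    "softmax",
    "log_softmax",
    "layer_norm",
    "gelu",
    "relu",
    "dropout",
    "embedding",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )
        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            return (g * exponent * self.data ** (exponent - 1.0),)
        return Tensor._make(self.data**exponent, (self,), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            return (g * out_data,)
        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)
        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g):
            return (g * (1.0 - out_data**2),)
        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g_arr = np.asarray(g)
            if not keepdims:
                g_arr = np.expand_dims(g_arr, axis)
            return (np.broadcast_to(g_arr, self.shape).copy(),)
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        def backward(g):
            return (g.reshape(self.shape),)
        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)
        def backward(g):
            return (g.transpose(inv),)
        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            return (grad,)
        return Tensor._make(self.data[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` (summed if non-scalar) into leaves."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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

        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node.grad += g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self):
        self.grad = None


# -- free functions ------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
    return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)


def _masked_softmax_data(x: np.ndarray, bias: np.ndarray | None, axis: int):
    z = x if bias is None else x + bias
    zmax = np.max(z, axis=axis, keepdims=True)
    # rows that are entirely -inf would produce nan; callers guarantee >=1
    # permitted position per row
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)
    e = np.exp(z - zmax)
    return e / e.sum(axis=axis, keepdims=True)


def softmax(x: Tensor, axis: int = -1, bias: np.ndarray | None = None) -> Tensor:
    """Softmax along ``axis`` with an optional additive mask ``bias``.

    ``bias`` is a constant array (broadcastable to ``x``) holding ``-inf`` at
    forbidden positions; those positions receive exactly zero probability and
    exactly zero gradient.
    """
    s = _masked_softmax_data(x.data, bias, axis)
    def backward(g):
        dot = np.sum(g * s, axis=axis, keepdims=True)
        return (s * (g - dot),)
    return Tensor._make(s, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    zmax = np.max(x.data, axis=axis, keepdims=True)
    z = x.data - zmax
    lse = np.log(np.sum(np.exp(z), axis=axis, keepdims=True))
    out_data = z - lse
    s = np.exp(out_data)
    def backward(g):
        return (g - s * np.sum(g, axis=axis, keepdims=True),)
    return Tensor._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then scale+shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data
    n = x.data.shape[-1]
    def backward(g):
        gxhat = g * gamma.data
        gx = inv / n * (
            n * gxhat
            - gxhat.sum(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
        )
        ggamma = _unbroadcast(g * xhat, gamma.shape)
        gbeta = _unbroadcast(g, beta.shape)
        return (gx, ggamma, gbeta)
    return Tensor._make(out_data, (x, gamma, beta), backward)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian Error Linear Unit: x * Phi(x)."""
    phi = 0.5 * (1.0 + _erf(x.data / _SQRT2))
    out_data = x.data * phi
    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data**2)
        return (g * (phi + x.data * pdf),)
    return Tensor._make(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    def backward(g):
        return (g * mask,)
    return Tensor._make(x.data * mask, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    def backward(g):
        return (g * keep,)
    return Tensor._make(x.data * keep, (x,), backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    def backward(g):
        grad = np.zeros_like(table.data)
        np.add.at(grad, ids, g)
        return (grad,)
    return Tensor._make(table.data[ids], (table,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def clip_gradients(params: list["Tensor"], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm. Stabilizes Adam against the loss spikes a
    post-norm Transformer produces early in training.
    """
    sq = 0.0
    for p in params:
        if p.grad is not None:
            sq += float((p.grad ** 2).sum())
    norm = math.sqrt(sq)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
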