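"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the generative
models in this package need: broadcasting arithmetic, (batched) matmul,
elementwise nonlinearities, reductions, shape manipulation, softmax, and a
fused pairwise-distance op for turning coordinate tensors into distance
features.  Gradients are accumulated into ``Tensor.grad`` by ``backward()``
over a topologically sorted graph.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

_DTYPE = np.float64


def default_dtype():
    return _DTYPE


@contextlib.contextmanager
def dtype_context(dtype):
    """Temporarily set the dtype newly created Tensors are cast to.

    float64 (the default) is used for gradient checks and small exact
    computations; training runs in float32 for speed.
    """
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
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

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward: Optional[Callable] = None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only valid for scalars")
            grad = np.ones_like(self.data)
        topo: list = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))
        out._backward = (lambda g: self._accum(g * p * self.data**(p - 1))
                         if self.requires_grad else None)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        def bw(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(t, (int, slice, type(Ellipsis))) for t in idx)
        )
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:
                    full[idx] = g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = (lambda g: self._accum(g.reshape(self.data.shape))
                         if self.requires_grad else None)
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)
        out._backward = (lambda g: self._accum(g.transpose(*inv))
                         if self.requires_grad else None)
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))
        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unary(x: Tensor, value: np.ndarray, dfn: Callable[[], np.ndarray]) -> Tensor:
    out = Tensor(value, x.requires_grad, (x,))
    out._backward = (lambda g: x._accum(g * dfn())) if x.requires_grad else None
    return out


def exp(x: Tensor) -> Tensor:
    v = np.exp(x.data)
    return _unary(x, v, lambda: v)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.data), lambda: 1.0 / x.data)


def sqrt(x: Tensor) -> Tensor:
    v = np.sqrt(x.data)
    return _unary(x, v, lambda: 0.5 / v)


def sigmoid(x: Tensor) -> Tensor:
    # clamp away from exactly 0/1 so downstream log() stays finite at the
    # working precision
    eps = np.finfo(x.data.dtype).eps
    v = np.clip(1.0 / (1.0 + np.exp(-x.data)), eps, 1.0 - eps)
    return _unary(x, v, lambda: v * (1.0 - v))


def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.data)
    return _unary(x, v, lambda: 1.0 - v * v)


def relu(x: Tensor) -> Tensor:
    return _unary(x, np.maximum(x.data, 0.0), lambda: (x.data > 0).astype(float))


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    v = np.where(x.data > 0, x.data, slope * x.data)
    return _unary(x, v, lambda: np.where(x.data > 0, 1.0, slope))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    v = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(v, x.requires_grad, (x,))
    def bw(g):
        if x.requires_grad:
            x._accum(v * (g - (g * v).sum(axis=axis, keepdims=True)))
    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bw
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis (fused forward/backward)."""
    d = x.data.shape[-1]
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data,
                 x.requires_grad or gain.requires_grad or bias.requires_grad,
                 (x, gain, bias))
    def bw(g):
        if gain.requires_grad:
            gain._accum((g * xhat).reshape(-1, d).sum(axis=0))
        if bias.requires_grad:
            bias._accum(g.reshape(-1, d).sum(axis=0))
        if x.requires_grad:
            gh = g * gain.data
            x._accum(inv * (gh - gh.mean(axis=-1, keepdims=True)
                            - xhat * (gh * xhat).mean(axis=-1, keepdims=True)))
    out._backward = bw
    return out


def affine(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Fused x @ W + b with hand-written backward."""
    out = Tensor(x.data @ weight.data + bias.data,
                 x.requires_grad or weight.requires_grad or bias.requires_grad,
                 (x, weight, bias))
    def bw(g):
        if x.requires_grad:
            x._accum(g @ weight.data.T)
        if weight.requires_grad:
            weight._accum(x.data.reshape(-1, x.data.shape[-1]).T
                          @ g.reshape(-1, g.shape[-1]))
        if bias.requires_grad:
            bias._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
    out._backward = bw
    return out


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, scale: float) -> Tensor:
    """Fused softmax(q k^T * scale) v over the last two axes.

    q, k, v: (..., L, d); returns (..., L, d).  One node instead of the
    softmax/matmul chain, with the standard closed-form backward.
    """
    s = (q.data @ np.swapaxes(k.data, -1, -2)) * scale
    s -= s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    att = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(att @ v.data,
                 q.requires_grad or k.requires_grad or v.requires_grad, (q, k, v))
    def bw(g):
        gatt = g @ np.swapaxes(v.data, -1, -2)
        gs = att * (gatt - (gatt * att).sum(axis=-1, keepdims=True))
        if v.requires_grad:
            v._accum(np.swapaxes(att, -1, -2) @ g)
        if q.requires_grad:
            q._accum((gs @ k.data) * scale)
        if k.requires_grad:
            k._accum((np.swapaxes(gs, -1, -2) @ q.data) * scale)
    out._backward = bw
    return out


def pairwise_distances(coords: Tensor, idx_i: np.ndarray, idx_j: np.ndarray,
                       eps: float = 1e-12) -> Tensor:
    """Distances ||r_i - r_j|| for index pairs, from a (..., L, 3) coordinate tensor.

    Returns a (..., P) tensor in the order of ``idx_i``/``idx_j``; gradients
    flow back into the coordinates.
    """
    diff = coords.data[..., idx_i, :] - coords.data[..., idx_j, :]
    d = np.sqrt(np.maximum((diff**2).sum(axis=-1), eps))
    out = Tensor(d, coords.requires_grad, (coords,))
    L = coords.data.shape[-2]
    def bw(g):
        if not coords.requires_grad:
            return
        gd = (g / d)[..., None] * diff                      # (..., P, 3)
        inc = np.zeros((L, len(idx_i)))                     # signed incidence
        inc[idx_i, np.arange(len(idx_i))] = 1.0
        inc[idx_j, np.arange(len(idx_j))] = -1.0
        coords._accum(np.einsum("lp,...pd->...ld", inc, gd, optimize=True))
    out._backward = bw
    return out
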