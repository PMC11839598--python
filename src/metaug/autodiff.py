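"""A small reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the metaug models need: broadcast-aware
elementwise arithmetic, matrix products, slicing, concatenation, reductions,
the usual nonlinearities, a fused row-softmax and a numerically stable
binary cross-entropy on logits.  Everything runs in float64.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .errors import NumericError

Array = np.ndarray


def _as_array(x) -> Array:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[Array], None] | None = None,
        name: str = "",
    ):
        self.value = _as_array(value)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward
        self.name = name

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accumulate(self, grad: Array) -> None:
        # assign-or-add: never mutate an incoming gradient array in place,
        # since it may be shared with sibling nodes
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        if self.value.size != 1:
            raise NumericError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def _lift(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.value**exponent, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.value ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, _parents=(self, other))

        def bwd(g):
            # 1-D operands follow numpy's matmul promotion rules, where the
            # dropped axis turns the usual transposed products into outer
            # products (vector @ matrix) or elementwise scaling (dot)
            a, b = self.value, other.value
            if self.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    self._accumulate(g * b)
                elif b.ndim == 1:
                    self._accumulate(np.outer(g, b))
                else:
                    self._accumulate(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1 and b.ndim == 1:
                    other._accumulate(g * a)
                elif a.ndim == 1:
                    other._accumulate(np.outer(a, g))
                else:
                    other._accumulate(a.T @ g)

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.T)
        return out

    def __getitem__(self, key):
        out = Tensor(self.value[key], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.shape)
        )
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.value)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - y * y)
        )
        return out

    def sigmoid(self):
        y = _sigmoid(self.value)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * y * (1.0 - y)
        )
        return out

    def relu(self):
        y = np.maximum(self.value, 0.0)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (self.value > 0.0)
        )
        return out

    def exp(self):
        y = np.exp(self.value)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.value), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g / self.value
        )
        return out


def _sigmoid(x: Array) -> Array:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def parameter(value, name: str = "") -> Tensor:
    return Tensor(value, requires_grad=True, name=name)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    values = [t.value for t in tensors]
    out = Tensor(np.concatenate(values, axis=axis), _parents=tuple(tensors))
    sizes = [v.shape[axis] for v in values]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def bmm(a: Tensor, b: Tensor, transpose_b: bool = False) -> Tensor:
    """Batched matrix product over stacked matrices: (..., m, k) @ (..., k, n).

    With ``transpose_b`` the last two axes of ``b`` are swapped first, which
    is how attention scores Q·Kᵀ are formed without materializing Kᵀ."""
    bv = np.swapaxes(b.value, -1, -2) if transpose_b else b.value
    out = Tensor(np.matmul(a.value, bv), _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(np.matmul(g, np.swapaxes(bv, -1, -2)))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.value, -1, -2), g)
            b._accumulate(np.swapaxes(gb, -1, -2) if transpose_b else gb)

    out._backward = bwd
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax over the last axis (fused primitive)."""
    shifted = x.value - x.value.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=-1, keepdims=True)
            x._accumulate(y * (g - dot))

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: Array) -> Tensor:
    """Mean binary cross-entropy from logits; gradient is sigmoid(z) - y."""
    z = logits.value
    t = _as_array(targets)
    if z.shape != t.shape:
        raise NumericError(f"shape mismatch: logits {z.shape} vs targets {t.shape}")
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if not np.all(np.isfinite(loss)):
        raise NumericError("non-finite loss")
    out = Tensor(loss.mean(), _parents=(logits,))
    n = max(z.size, 1)

    def bwd(g):
        if logits.requires_grad:
            logits._accumulate(g * (_sigmoid(z) - t) / n)

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer with an optional cosine learning-rate schedule."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-2,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        schedule: str = "constant",
        total_steps: int | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.schedule = schedule
        self.total_steps = total_steps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def current_lr(self) -> float:
        if self.schedule == "cosine" and self.total_steps:
            frac = min(self.t / self.total_steps, 1.0)
            return self.lr * 0.5 * (1.0 + np.cos(np.pi * frac))
        return self.lr

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr()
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
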