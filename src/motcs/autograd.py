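"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements the small set of tensor operations the MOTCS network needs
(broadcast arithmetic, batched matmul, ReLU/leaky-ReLU, exp/log/pow,
reductions, reshape/transpose, concatenation) with a tape built implicitly
through parent links and gradients propagated in reverse topological order.
Parameters and activations are plain ``float64`` arrays wrapped in
:class:`Tensor`; everything is deterministic given the caller's RNG.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
        requires_grad: bool = True,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.array(g)  # copy: g may alias a child's buffer
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g: Array) -> None:
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g: Array) -> None:
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g: Array) -> None:
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bw(g: Array) -> None:
            self._accum(
                _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)),
                             self.data.shape)
            )
            other._accum(
                _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g),
                             other.data.shape)
            )

        out._backward = bw
        return out

    # ------------------------------------------------------------ nonlinearity
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, alpha: float = 0.01) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, alpha * self.data), (self,))
        out._backward = lambda g: self._accum(g * np.where(mask, 1.0, alpha))
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, (self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g: Array) -> None:
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out


def as_tensor(x) -> Tensor:
    """Wrap scalars/arrays as constant tensors; pass tensors through."""
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis`` with gradient split back to the parts."""
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g: Array) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (shift by a detached max)."""
    shift = as_tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * as_tensor(mask)


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
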