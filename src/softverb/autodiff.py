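"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the tiny masked language model and the BiLSTM
prompt encoder are trained with.  It is deliberately small: dense float64
tensors, a handful of differentiable primitives (enough for attention,
LSTMs, layer normalisation and cross-entropy), and an AdamW optimizer.
Gradients only propagate into tensors created with ``requires_grad=True``
(parameters); everything reachable only from constants is skipped, so
running a forward pass over constants costs no backward bookkeeping.

All primitives are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "concat",
    "stack",
    "embedding",
    "layer_norm",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- graph construction helpers ------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        if not self.requires_grad:
            return Tensor(-self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(-g)

        return Tensor(-self.data, True, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, True, (self, other), backward)

    def pow_const(self, c: float) -> "Tensor":
        out_data = self.data ** c
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * c * self.data ** (c - 1.0))

        return Tensor(out_data, True, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------
    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * (1.0 - out_data * out_data))

        return Tensor(out_data, True, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * out_data)

        return Tensor(out_data, True, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(g / self.data)

        return Tensor(out_data, True, (self,), backward)

    # -- reductions and shaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(out_data, True, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(g.reshape(self.data.shape))

        return Tensor(out_data, True, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(np.swapaxes(g, a, b))

        return Tensor(out_data, True, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return Tensor(out_data, True, (self,), backward)

    # -- softmax family -------------------------------------------------
    def log_softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        if not self.requires_grad:
            return Tensor(out_data)
        soft = np.exp(out_data)

        def backward(g: np.ndarray) -> None:
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor(out_data, True, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        out_data = e / e.sum(axis=axis, keepdims=True)
        if not self.requires_grad:
            return Tensor(out_data)

        def backward(g: np.ndarray) -> None:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor(out_data, True, (self,), backward)

    # -- backward pass ----------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        if not self.requires_grad:
            raise ValueError("loss does not depend on any parameter")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Create a trainable tensor.

    With ``rng`` and ``scale``, ``data`` is interpreted as a shape and the
    parameter is drawn from N(0, scale^2).
    """
    if rng is not None:
        data = rng.normal(0.0, scale if scale is not None else 0.02, size=data)
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, True, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    if not req:
        return Tensor(out_data)

    def backward(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor(out_data, True, tuple(tensors), backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient into the table."""
    ids = np.asarray(ids, dtype=np.intp)
    out_data = table.data[ids]
    if not table.requires_grad:
        return Tensor(out_data)

    def backward(g: np.ndarray) -> None:
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, ids, g)

    return Tensor(out_data, True, (table,), backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = (var + eps).pow_const(-0.5)
    return centered * inv * gain + bias


class AdamW:
    """AdamW: Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
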