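"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a transformer: broadcast-aware arithmetic,
batched matmul, reshapes/transposes, reductions, relu, stable
(log-)softmax, embedding lookup and gather.  Gradients are accumulated by
topologically-sorted backward passes over a dynamically built tape; a
`no_grad` context disables taping for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = backward
        self._parents = parents if self.requires_grad else ()
        self.name = name

    # ---- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ---- ops ------------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data
        rq = self.requires_grad or other.requires_grad
        if not (rq and _GRAD_ENABLED):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data
        rq = self.requires_grad or other.requires_grad
        if not (rq and _GRAD_ENABLED):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor(out_data, True, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = np.matmul(self.data, other.data)
        rq = self.requires_grad or other.requires_grad
        if not (rq and _GRAD_ENABLED):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        orig = self.data.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor(out_data, True, (self,), bwd)

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        out_data = np.transpose(self.data, axes)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        inv = tuple(np.argsort(axes))

        def bwd(g):
            self._accum(np.transpose(g, inv))

        return Tensor(out_data, True, (self,), bwd)

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        shape = self.data.shape

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor(out_data, True, (self,), bwd)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        shifted = x - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        softmax = np.exp(out_data)

        def bwd(g):
            self._accum(g - softmax * g.sum(axis=axis, keepdims=True))

        return Tensor(out_data, True, (self,), bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        e = np.exp(x - x.max(axis=axis, keepdims=True))
        out_data = e / e.sum(axis=axis, keepdims=True)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)

        def bwd(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor(out_data, True, (self,), bwd)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup `weight[idx]` with scatter-add gradient."""
    idx = np.asarray(idx)
    out_data = weight.data[idx]
    if not (weight.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bwd(g):
        if weight.grad is None:
            weight.grad = np.zeros_like(weight.data)
        np.add.at(weight.grad, idx, g)

    return Tensor(out_data, True, (weight,), bwd)


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick `x[..., idx]` elementwise along the last axis (e.g. token logprobs)."""
    idx = np.asarray(idx)
    out_data = np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0]
    if not (x.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)

    def bwd(g):
        full = np.zeros_like(x.data)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        x._accum(full)

    return Tensor(out_data, True, (x,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis (fused primitive with
    analytic gradient: cheaper than composing eight tape nodes)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    centred = x.data - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centred * inv
    out_data = xhat * gamma.data + beta.data
    rq = x.requires_grad or gamma.requires_grad or beta.requires_grad
    if not (rq and _GRAD_ENABLED):
        return Tensor(out_data)

    def bwd(g):
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if x.requires_grad:
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            x._accum((gy - m1 - xhat * m2) * inv)

    return Tensor(out_data, True, (x, gamma, beta), bwd)


class Adam:
    """Adam optimiser with optional global gradient-norm clipping."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 1.0,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.clip_norm = lr, betas, eps, clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        if self.clip_norm is not None:
            total = float(
                np.sqrt(sum((p.grad ** 2).sum() for p in self.params if p.grad is not None))
            )
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
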