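"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the package's sequence-to-sequence and
convolutional models need: broadcast-aware arithmetic, (batched) matmul,
embedding lookup, layer normalisation, softmax, max-pooling, concatenation
and fused cross-entropy losses.  Gradients accumulate into ``Tensor.grad``
on ``backward()`` over the reverse topological order of the recorded graph.

All computation is float64: model training at desk scale is cheap, and exact
closed-form checks (e.g. perplexity of a uniform model) stay tight.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        prev: tuple["Tensor", ...] = (),
        backward: Callable[[], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = backward
        self._prev = prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward()

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_wrap(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw():
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        out._backward = bw
        return out

    def swap_last2(self):
        nd = self.data.ndim
        axes = list(range(nd))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.transpose(*axes)

    # -- reductions / nonlinearities ----------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(np.broadcast_to(out.grad, self.data.shape).copy())

        out._backward = bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out._backward = bw
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* over the axes that numpy broadcasting introduced."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# fused operations


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], weight.requires_grad, (weight,))

    def bw():
        if weight.requires_grad:
            g = np.zeros_like(weight.data)
            np.add.at(g, idx.reshape(-1), out.grad.reshape(-1, weight.data.shape[-1]))
            weight._accum(g)

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(
        xhat * gamma.data + beta.data,
        x.requires_grad or gamma.requires_grad or beta.requires_grad,
        (x, gamma, beta),
    )
    d = x.data.shape[-1]

    def bw():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gx = g * gamma.data
            term = (
                gx
                - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accum(term)

    out._backward = bw
    return out


def softmax_last(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            g = out.grad
            dot = (g * y).sum(axis=-1, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = bw
    return out


def max_axis(x: Tensor, axis: int) -> Tensor:
    amax = x.data.argmax(axis=axis)
    out_data = np.take_along_axis(x.data, np.expand_dims(amax, axis), axis).squeeze(
        axis
    )
    out = Tensor(out_data, x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.put_along_axis(
                g, np.expand_dims(amax, axis), np.expand_dims(out.grad, axis), axis
            )
            x._accum(g)

    out._backward = bw
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]

    def bw():
        offs = np.cumsum([0] + sizes)
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def log_softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def cross_entropy_logits(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray
) -> Tensor:
    """Mean masked negative log-likelihood of *targets* under *logits*.

    ``logits``: (N, V); ``targets``: (N,) int; ``mask``: (N,) float {0, 1}.
    """
    n = max(mask.sum(), 1.0)
    logp = log_softmax_np(logits.data)
    idx = np.arange(targets.shape[0])
    nll = -(logp[idx, targets] * mask).sum() / n
    out = Tensor(nll, logits.requires_grad, (logits,))

    def bw():
        if logits.requires_grad:
            p = np.exp(logp)
            g = p * mask[:, None]
            g[idx, targets] -= mask
            logits._accum(out.grad * g / n)

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores; numerically stable."""
    z = logits.data
    loss = np.maximum(z, 0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), logits.requires_grad, (logits,))

    def bw():
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accum(out.grad * (sig - targets) / z.size)

    out._backward = bw
    return out
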