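"""Neural layers and the Adam optimiser, built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    concat,
    dropout,
    embedding,
    layer_norm,
    max_axis,
    softmax_last,
)

NEG_INF = -1e9


class Module:
    """Base class: parameter collection and flat state dict for checkpoints."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            params.extend(_collect(v))
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in vars(self).items():
            out.update(_collect_named(v, f"{prefix}{k}"))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named_parameters()
        if set(named) != set(state):
            missing = set(named) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for k, p in named.items():
            p.data[...] = state[k]


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, name: str) -> dict[str, Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return {name: v}
    if isinstance(v, Module):
        return v.named_parameters(prefix=name + ".")
    if isinstance(v, (list, tuple)):
        out = {}
        for i, item in enumerate(v):
            out.update(_collect_named(item, f"{name}.{i}"))
        return out
    return {}


def param(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.w = param(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n: int, d: int):
        self.w = Tensor(rng.normal(0.0, 0.02, size=(n, d)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.w, idx)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with h heads over (B, T, D) inputs."""

    def __init__(self, rng: np.random.Generator, d_model: int, n_heads: int):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(
        self, q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None
    ) -> Tensor:
        B, Tq, D = q.shape
        Tk = k.shape[1]
        qh = self._split(self.wq(q), B, Tq)
        kh = self._split(self.wk(k), B, Tk)
        vh = self._split(self.wv(v), B, Tk)
        scores = (qh @ kh.swap_last2()) * (1.0 / np.sqrt(self.d_head))
        if mask is not None:
            scores = scores + Tensor(mask)  # additive, NEG_INF on blocked keys
        attn = softmax_last(scores)
        out = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, rng: np.random.Generator, d_model: int, d_ff: int):
        self.l1 = Linear(rng, d_model, d_ff)
        self.l2 = Linear(rng, d_ff, d_model)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())


class EncoderLayer(Module):
    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        self.attn = MultiHeadAttention(rng, d_model, n_heads)
        self.ffn = FeedForward(rng, d_model, d_ff)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None) -> Tensor:
        x = self.ln1(x + self.attn(x, x, x, pad_mask))
        return self.ln2(x + self.ffn(x))


class DecoderLayer(Module):
    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        self.self_attn = MultiHeadAttention(rng, d_model, n_heads)
        self.cross_attn = MultiHeadAttention(rng, d_model, n_heads)
        self.ffn = FeedForward(rng, d_model, d_ff)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ln3 = LayerNorm(d_model)

    def __call__(
        self,
        x: Tensor,
        enc: Tensor,
        causal_mask: np.ndarray,
        cross_mask: np.ndarray | None,
    ) -> Tensor:
        x = self.ln1(x + self.self_attn(x, x, x, causal_mask))
        x = self.ln2(x + self.cross_attn(x, enc, enc, cross_mask))
        return self.ln3(x + self.ffn(x))


def causal_mask(T: int) -> np.ndarray:
    """(1, 1, T, T) additive mask blocking attention to future positions."""
    m = np.triu(np.full((T, T), NEG_INF), k=1)
    return m[None, None, :, :]


def pad_mask(lengths: np.ndarray, T: int) -> np.ndarray:
    """(B, 1, 1, T) additive mask blocking attention to padding keys."""
    ar = np.arange(T)[None, :]
    blocked = ar >= lengths[:, None]
    return np.where(blocked, NEG_INF, 0.0)[:, None, None, :]


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = [
    "Adam",
    "DecoderLayer",
    "Embedding",
    "EncoderLayer",
    "FeedForward",
    "LayerNorm",
    "Linear",
    "Module",
    "MultiHeadAttention",
    "NEG_INF",
    "causal_mask",
    "concat",
    "dropout",
    "max_axis",
    "pad_mask",
    "param",
]
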