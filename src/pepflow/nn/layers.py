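"""Neural building blocks on the autodiff engine: linear/embedding layers,
layer norm, multi-head attention, transformer encoder/decoder layers, Adam."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor, embedding, layernorm, log_softmax, maybe_dropout

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MultiHeadAttention",
    "FeedForward",
    "EncoderLayer",
    "DecoderLayer",
    "Adam",
    "attention_bias",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery (for the optimizer and
    checkpoint serialization)."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"checkpoint/model parameter mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n, d)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(d))
        self.shift = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layernorm(x, self.gain, self.shift, self.eps)


def attention_bias(valid_mask: np.ndarray | None) -> np.ndarray | None:
    """Additive bias (B, 1, 1, N) from a boolean validity mask (B, N)."""
    if valid_mask is None:
        return None
    bias = np.where(valid_mask, 0.0, -1e9)
    return bias[:, None, None, :]


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("n_heads must divide d_model")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.o_proj = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(
        self,
        query: Tensor,
        memory: Tensor,
        memory_mask: np.ndarray | None = None,
    ) -> Tensor:
        B, Tq, d = query.shape
        Tk = memory.shape[1]
        q = self._split(self.q_proj(query), B, Tq)
        k = self._split(self.k_proj(memory), B, Tk)
        v = self._split(self.v_proj(memory), B, Tk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_head))
        bias = attention_bias(memory_mask)
        if bias is not None:
            scores = scores + bias
        attn = log_softmax(scores, axis=-1).exp()
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, Tq, d)
        return maybe_dropout(self.o_proj(out))


class FeedForward(Module):
    def __init__(self, d_model: int, d_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return maybe_dropout(self.fc2(maybe_dropout(self.fc1(x).gelu())))


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer (self-attention + FFN)."""

    def __init__(self, d_model: int, n_heads: int, d_hidden: int, rng):
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm2 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_hidden, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, mask)
        x = x + self.ffn(self.norm2(x))
        return x


class DecoderLayer(Module):
    """Pre-norm transformer decoder layer with *non-causal* self-attention and
    cross-attention to a memory sequence."""

    def __init__(self, d_model: int, n_heads: int, d_hidden: int, rng):
        self.norm1 = LayerNorm(d_model)
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm2 = LayerNorm(d_model)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm3 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_hidden, rng)

    def __call__(
        self,
        x: Tensor,
        memory: Tensor,
        self_mask: np.ndarray | None = None,
        memory_mask: np.ndarray | None = None,
    ) -> Tensor:
        h = self.norm1(x)
        x = x + self.self_attn(h, h, self_mask)
        x = x + self.cross_attn(self.norm2(x), memory, memory_mask)
        x = x + self.ffn(self.norm3(x))
        return x


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 1.0,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:  # decoupled; skip biases/norms
                p.data -= self.lr * self.weight_decay * p.data
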