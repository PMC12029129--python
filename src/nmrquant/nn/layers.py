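"""Neural-network building blocks on top of the autograd engine.

Initialization is fan-in scaled uniform (U(-1/sqrt(fan_in), +1/sqrt(fan_in)))
and driven by an explicit numpy Generator so model construction is exactly
reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "sinusoidal_positional_encoding",
    "ACTIVATIONS",
]


def ACTIVATIONS(name: str):
    """Map an activation name to a Tensor -> Tensor callable."""
    table = {
        "relu": lambda t: t.relu(),
        "leakyrelu": lambda t: t.leaky_relu(0.01),
        "elu": lambda t: t.elu(1.0),
    }
    key = name.lower().replace("_", "")
    if key not in table:
        raise ValueError(f"unknown activation {name!r}; use one of {sorted(table)}")
    return table[key]


class Module:
    """Minimal container: tracks parameters of itself and sub-modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype, copy=True)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    bound = 1.0 / np.sqrt(fan_in) if fan_in > 0 else 0.0
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = _fan_in_uniform(rng, (n_in, n_out), n_in, dtype)
        self.bias = _fan_in_uniform(rng, (n_out,), n_in, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalization over the last axis with learned affine parameters."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


def sinusoidal_positional_encoding(seq_len: int, dim: int, dtype=np.float32) -> np.ndarray:
    """Fixed sin/cos positional encodings: PE[p, 2i] = sin(p / 10000^(2i/d))."""
    pos = np.arange(seq_len)[:, None].astype(float)
    i = np.arange(0, dim, 2).astype(float)
    angles = pos / np.power(10000.0, i / dim)
    pe = np.zeros((seq_len, dim))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles[:, : dim // 2])
    return pe.astype(dtype)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention with ``n_heads`` heads."""

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        if embed_dim % n_heads != 0:
            raise ValueError(f"embed_dim {embed_dim} not divisible by n_heads {n_heads}")
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.q_proj = Linear(embed_dim, embed_dim, rng, dtype)
        self.k_proj = Linear(embed_dim, embed_dim, rng, dtype)
        self.v_proj = Linear(embed_dim, embed_dim, rng, dtype)
        self.out_proj = Linear(embed_dim, embed_dim, rng, dtype)

    def _split(self, t: Tensor, B: int, S: int) -> Tensor:
        # (B, S, E) -> (B, H, S, head_dim)
        return t.reshape(B, S, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, S, E = x.shape
        q = self._split(self.q_proj(x), B, S)
        k = self._split(self.k_proj(x), B, S)
        v = self._split(self.v_proj(x), B, S)
        scores = (q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(self.head_dim))
        att = scores.softmax(axis=-1)
        out = att @ v  # (B, H, S, head_dim)
        out = out.transpose(0, 2, 1, 3).reshape(B, S, E)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: self-attention and feedforward sublayers,
    each wrapped in a residual connection followed by layer normalization.
    No dropout is applied anywhere."""

    def __init__(self, embed_dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.attn = MultiheadSelfAttention(embed_dim, n_heads, rng, dtype)
        self.norm1 = LayerNorm(embed_dim, dtype=dtype)
        self.ff1 = Linear(embed_dim, ff_dim, rng, dtype)
        self.ff2 = Linear(ff_dim, embed_dim, rng, dtype)
        self.norm2 = LayerNorm(embed_dim, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        x = self.norm2(x + self.ff2(self.ff1(x).relu()))
        return x
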