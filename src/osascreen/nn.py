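"""Neural building blocks on top of the autodiff engine.

Blocks follow the post-norm transformer convention: residual connection,
then layer normalization, then dropout after each sub-layer. Dropout is
active only when a train-time RNG is passed to ``forward``; evaluation
passes ``rng=None`` and is fully deterministic.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, layer_norm, softmax

__all__ = [
    "Module", "Linear", "LayerNorm", "FeedForward", "MultiHeadAttention",
    "EncoderBlock", "DecoderBlock", "dropout", "causal_mask",
]


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when `rng` is None (evaluation) or rate 0."""
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64)
    return x * Tensor(keep / (1.0 - rate))


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for key, value in vars(self).items():
            for sub, p in _collect_named(value):
                out[f"{key}{sub}"] = p
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_named(value, prefix=""):
    if isinstance(value, Tensor) and value.requires_grad:
        yield prefix, value
    elif isinstance(value, Module):
        for k, v in value.named_parameters().items():
            yield f"{prefix}.{k}", v
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _collect_named(v, f"{prefix}.{i}")


def _uniform_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    """Affine map y = x W + b applied over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(_uniform_init(rng, d_in, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.bias = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias, eps=self.eps)


class FeedForward(Module):
    """Position-wise two-layer network with ReLU."""

    def __init__(self, d_model: int, d_ffn: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ffn, rng)
        self.fc2 = Linear(d_ffn, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def causal_mask(n: int) -> np.ndarray:
    """Additive mask forbidding attention to future positions."""
    return np.triu(np.full((n, n), -1e9), k=1)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """softmax(q k^T / sqrt(d_k)) v; returns (output, weights)."""
    d_k = q.shape[-1]
    scores = (q @ k.transpose()) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        scores = scores + Tensor(mask)
    weights = softmax(scores, axis=-1)
    return weights @ v, weights


class MultiHeadAttention(Module):
    """Standard multi-head scaled dot-product attention.

    Operates on (..., T, d_model) tensors; heads are realized by reshaping
    the projected tensors to (..., n_heads, T, d_head).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.proj_q = Linear(d_model, d_model, rng)
        self.proj_k = Linear(d_model, d_model, rng)
        self.proj_v = Linear(d_model, d_model, rng)
        self.proj_out = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        *lead, t, d = x.shape
        x = x.reshape(*lead, t, self.n_heads, self.d_head)
        return x.transpose(-3, -2)  # (..., heads, T, d_head)

    def _merge(self, x: Tensor) -> Tensor:
        x = x.transpose(-3, -2)
        *lead, t, h, dh = x.shape
        return x.reshape(*lead, t, h * dh)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 mask: np.ndarray | None = None) -> Tensor:
        q = self._split(self.proj_q(query))
        k = self._split(self.proj_k(key))
        v = self._split(self.proj_v(value))
        out, _ = scaled_dot_attention(q, k, v, mask=mask)
        return self.proj_out(self._merge(out))


class EncoderBlock(Module):
    """Self-attention + feed-forward, post-norm, dropout after each sub-layer."""

    def __init__(self, d_model: int, n_heads: int, d_ffn: int,
                 rate: float, rng: np.random.Generator):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ffn, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = dropout(self.norm1(x + self.attn(x, x, x)), self.rate, rng)
        x = dropout(self.norm2(x + self.ffn(x)), self.rate, rng)
        return x


class DecoderBlock(Module):
    """Masked self-attention, cross-attention over the memory, feed-forward."""

    def __init__(self, d_model: int, n_heads: int, d_ffn: int,
                 rate: float, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ffn, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.norm3 = LayerNorm(d_model)
        self.rate = rate

    def __call__(self, x: Tensor, memory: Tensor,
                 rng: np.random.Generator | None = None) -> Tensor:
        n = x.shape[-2]
        x = dropout(self.norm1(x + self.self_attn(x, x, x, mask=causal_mask(n))),
                    self.rate, rng)
        x = dropout(self.norm2(x + self.cross_attn(x, memory, memory)), self.rate, rng)
        x = dropout(self.norm3(x + self.ffn(x)), self.rate, rng)
        return x
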