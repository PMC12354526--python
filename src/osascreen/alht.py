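"""Auditory-Linguistic Hierarchical Transformer (ALHT).

The hierarchy has three stages. *Advanced acoustic encoding* projects the
spectrogram frames into model space, adds sinusoidal positional encodings,
suppresses residual broadband interference with a learnable temporal
convolution, re-weights frames with a single-head attention ("frame
weighting"), and refines the result with a transformer encoder stack.
*Dynamic contextual integration* attends from token/query states onto the
acoustic frames (temporal focus), fuses global sentence- and subject-level
embeddings with learnable scalars, and optionally recalibrates the focus
weights from decoder predictions. *Adaptive decoding* maps the aggregated
representation either to a binary risk decision (classifier head, the
default for screening) or to a token sequence via a transformer decoder with
beam search.

Losses: a cross-entropy decoding loss, a temporal-consistency loss (squared
distance between time-pooled acoustic and aggregated representations), and
their weighted combination L = lambda1 * L_ce + lambda2 * L_consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, as_tensor, softmax
from .nn import (DecoderBlock, EncoderBlock, FeedForward, LayerNorm, Linear,
                 Module, dropout)

__all__ = [
    "ModelConfig", "AttentionResult", "LossBreakdown", "FeatureProject",
    "positional_encoding", "positional_encode", "EncoderStack",
    "ConvNoiseSuppress", "FrameWeighting", "TemporalFocus",
    "ContextualAggregate", "CrossModalRefine", "ClassifierHead",
    "TokenDecoder", "beam_search", "linguistic_loss", "consistency_loss",
    "total_loss", "cross_entropy",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss hyperparameters.

    The full-scale defaults (6+6 layers, 8 heads, hidden size 512, FFN 2048,
    dropout 0.2) describe the deployment-scale network; ``tiny()`` returns the
    desk-scale preset used throughout the tests and examples.
    """

    n_encoder_layers: int = 6
    n_decoder_layers: int = 6
    n_heads: int = 8
    d_model: int = 512
    d_ffn: int = 2048
    dropout: float = 0.2
    vocab: tuple[str, ...] = ("NEG", "POS", "EOS")
    head_mode: str = "classifier"          # or "token_sequence"
    lambda1: float = 1.0
    lambda2: float = 0.1
    positional_mode: str = "sinusoidal"    # or "learned", "sine_only"
    conv_width: int = 3
    n_query_tokens: int = 2
    tiny_preset: bool = False

    def validate(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.head_mode not in ("classifier", "token_sequence"):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")
        if self.conv_width % 2 != 1:
            raise ValueError("conv_width must be odd")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        base = cls(n_encoder_layers=2, n_decoder_layers=2, n_heads=2,
                   d_model=32, d_ffn=64, dropout=0.1, tiny_preset=True)
        return replace(base, **overrides)


@dataclass
class AttentionResult:
    """Row-stochastic attention weights with the attended output."""

    weights: np.ndarray
    attended: np.ndarray
    scores: np.ndarray | None = None


@dataclass
class LossBreakdown:
    """Per-term losses, their mixing weights and the combined objective."""

    total: Tensor
    terms: dict = field(default_factory=dict)      # name -> Tensor
    weights: dict = field(default_factory=dict)    # name -> float

    def value(self, name: str | None = None) -> float:
        if name is None:
            return float(self.total.data)
        return float(self.terms[name].data)


# --------------------------------------------------------------------------
# acoustic encoding
# --------------------------------------------------------------------------

class FeatureProject(Module):
    """Learnable per-frame affine projection into model space."""

    def __init__(self, d_in: int, d_model: int, rng: np.random.Generator):
        self.proj = Linear(d_in, d_model, rng)
        self.d_in = d_in

    def __call__(self, features) -> Tensor:
        x = as_tensor(features)
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected feature dim {self.d_in}, got {x.shape[-1]}")
        return self.proj(x)


def positional_encoding(n_positions: int, d_model: int,
                        mode: str = "sinusoidal") -> np.ndarray:
    """Sinusoidal position table P[t, 2k] = sin(t / 10000^(2k/d)).

    ``sinusoidal`` fills odd dimensions with the matching cosine (the
    standard interleave); ``sine_only`` uses the sine expression for every
    dimension, taking k = floor(dim/2).
    """
    pos = np.arange(n_positions)[:, None]
    k = np.arange(d_model)[None, :] // 2
    angle = pos / np.power(10000.0, 2.0 * k / d_model)
    if mode == "sine_only":
        return np.sin(angle)
    table = np.empty((n_positions, d_model))
    table[:, 0::2] = np.sin(angle[:, 0::2])
    table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


def positional_encode(x, mode: str = "sinusoidal") -> Tensor:
    """Add the positional table to a (..., T, d) tensor."""
    x = as_tensor(x)
    t, d = x.shape[-2], x.shape[-1]
    return x + Tensor(positional_encoding(t, d, mode=mode))


class EncoderStack(Module):
    """L successive transformer encoder blocks; 0 layers is the identity."""

    def __init__(self, n_layers: int, d_model: int, n_heads: int, d_ffn: int,
                 rate: float, rng: np.random.Generator):
        self.blocks = [EncoderBlock(d_model, n_heads, d_ffn, rate, rng)
                       for _ in range(n_layers)]

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for block in self.blocks:
            x = block(x, rng=rng)
        return x


def _shift_matrix(t: int, offset: int) -> np.ndarray:
    """S such that (S @ x)[i] = x[i + offset], zero-padded at the edges."""
    s = np.zeros((t, t))
    idx = np.arange(t)
    keep = (idx + offset >= 0) & (idx + offset < t)
    s[idx[keep], idx[keep] + offset] = 1.0
    return s


class ConvNoiseSuppress(Module):
    """Depthwise 1-D convolution along time (same-length, zero padding).

    Initialized to the identity kernel so that the stage starts as a
    pass-through and learns what interference to suppress.
    """

    def __init__(self, d_model: int, width: int = 3):
        if width % 2 != 1:
            raise ValueError("kernel width must be odd")
        kernel = np.zeros((width, d_model))
        kernel[width // 2] = 1.0
        self.kernel = Tensor(kernel, requires_grad=True)
        self.width = width

    def __call__(self, x: Tensor) -> Tensor:
        t = x.shape[-2]
        half = self.width // 2
        out = None
        for j in range(self.width):
            shifted = Tensor(_shift_matrix(t, j - half)) @ x
            term = shifted * self.kernel.take_rows([j]).reshape(1, -1)
            out = term if out is None else out + term
        return out


class FrameWeighting(Module):
    """Single-head self-attention re-weighting of frames (F_weighted = W V)."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.proj_q = Linear(d_model, d_model, rng)
        self.proj_k = Linear(d_model, d_model, rng)
        self.proj_v = Linear(d_model, d_model, rng)
        self.d_k = d_model

    def __call__(self, f_clean: Tensor) -> tuple[Tensor, AttentionResult]:
        q, k, v = self.proj_q(f_clean), self.proj_k(f_clean), self.proj_v(f_clean)
        scores = (q @ k.transpose()) * (1.0 / np.sqrt(self.d_k))
        weights = softmax(scores, axis=-1)
        out = weights @ v
        return out, AttentionResult(weights=weights.data, attended=out.data,
                                    scores=scores.data)


# --------------------------------------------------------------------------
# dynamic contextual integration
# --------------------------------------------------------------------------

class TemporalFocus(Module):
    """Cross-attention from token/query states onto acoustic frames."""

    def __init__(self, d_model: int, rng: np.random.Generator, d_key: int | None = None):
        d_key = d_key or d_model
        self.proj_q = Linear(d_model, d_key, rng)
        self.proj_k = Linear(d_model, d_key, rng)
        self.proj_v = Linear(d_model, d_model, rng)
        self.d_key = d_key

    def project_keys(self, acoustic: Tensor) -> Tensor:
        return self.proj_k(acoustic)

    def __call__(self, tokens: Tensor, acoustic: Tensor) -> tuple[AttentionResult, Tensor]:
        q = self.proj_q(tokens)
        k = self.proj_k(acoustic)
        v = self.proj_v(acoustic)
        scores = (q @ k.transpose()) * (1.0 / np.sqrt(self.d_key))
        weights = softmax(scores, axis=-1)
        c_focus = weights @ v
        return AttentionResult(weights=weights.data, attended=c_focus.data,
                               scores=scores.data), c_focus


class ContextualAggregate(Module):
    """C_agg = LayerNorm(C_focus + alpha*S + beta*E); C_final = FFN(C_agg) + C_agg.

    S is a global (sentence/session-level) embedding, E a subject-level
    embedding; alpha and beta are learnable scalars weighting their
    contributions.
    """

    def __init__(self, d_model: int, d_ffn: int, rng: np.random.Generator):
        self.alpha = Tensor(np.array(0.1), requires_grad=True)
        self.beta = Tensor(np.array(0.1), requires_grad=True)
        self.norm = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ffn, rng)

    def __call__(self, c_focus: Tensor, s: Tensor, e: Tensor) -> tuple[Tensor, Tensor]:
        c_agg = self.norm(c_focus + self.alpha * s + self.beta * e)
        c_final = self.ffn(c_agg) + c_agg
        return c_agg, c_final


class CrossModalRefine(Module):
    """Recalibrate focus weights from decoder predictions Y_pred."""

    def __init__(self, d_model: int, rng: np.random.Generator, d_key: int | None = None):
        d_key = d_key or d_model
        self.proj_q = Linear(d_model, d_key, rng)
        self.d_key = d_key

    def __call__(self, y_pred: Tensor, k_focus: Tensor) -> AttentionResult:
        scores = (self.proj_q(y_pred) @ k_focus.transpose()) * (1.0 / np.sqrt(self.d_key))
        weights = softmax(scores, axis=-1)
        return AttentionResult(weights=weights.data, attended=(weights @ k_focus).data,
                               scores=scores.data)


# --------------------------------------------------------------------------
# heads
# --------------------------------------------------------------------------

class ClassifierHead(Module):
    """Mean-pool over positions, linear map, softmax over {low, high} risk."""

    def __init__(self, d_model: int, rng: np.random.Generator, n_classes: int = 2):
        self.proj = Linear(d_model, n_classes, rng)

    def __call__(self, c_agg: Tensor) -> Tensor:
        pooled = c_agg.mean(axis=-2)
        return softmax(self.proj(pooled), axis=-1)

    def classify(self, c_agg: Tensor) -> tuple[np.ndarray, np.ndarray]:
        """Hard labels and confidences (max class probability)."""
        probs = self(c_agg).data
        labels = probs.argmax(axis=-1)
        return labels, probs.max(axis=-1)


class TokenDecoder(Module):
    """Autoregressive transformer decoder over a small token vocabulary."""

    START = 0  # reserved start-of-sequence embedding row

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        config.validate()
        d = config.d_model
        self.vocab = tuple(config.vocab)
        n_vocab = len(self.vocab)
        # row 0 is the start token; rows 1..n are vocabulary tokens
        self.embedding = Tensor(rng.normal(0, 0.5, size=(n_vocab + 1, d)),
                                requires_grad=True)
        self.blocks = [DecoderBlock(d, config.n_heads, config.d_ffn, config.dropout, rng)
                       for _ in range(config.n_decoder_layers)]
        self.w_out = Linear(d, n_vocab, rng)
        self.positional_mode = ("sinusoidal" if config.positional_mode == "learned"
                                else config.positional_mode)

    def _states(self, prefix_ids: list[int], memory: Tensor,
                rng: np.random.Generator | None = None) -> Tensor:
        ids = [self.START] + [i + 1 for i in prefix_ids]
        x = self.embedding.take_rows(ids)
        x = positional_encode(x, mode=self.positional_mode)
        for block in self.blocks:
            x = block(x, memory, rng=rng)
        return x

    def decode_step(self, prefix_ids: list[int], memory: Tensor,
                    rng: np.random.Generator | None = None) -> Tensor:
        """Next-token distribution P(y_i | y_<i, memory); sums to 1."""
        states = self._states(prefix_ids, memory, rng=rng)
        last = Tensor(np.eye(states.shape[-2])[-1:]) @ states  # select last row
        return softmax(self.w_out(last), axis=-1).reshape(-1)

    def sequence_distributions(self, target_ids: list[int], memory: Tensor,
                               rng: np.random.Generator | None = None) -> Tensor:
        """Teacher-forced per-step distributions, shape (len(target), vocab)."""
        states = self._states(target_ids[:-1] if target_ids else [], memory, rng=rng)
        return softmax(self.w_out(states), axis=-1)


def beam_search(model, memory, width: int, max_len: int,
                eos_id: int | None = None) -> list[int]:
    """Breadth-limited best-first decoding.

    Keeps the `width` highest joint-probability hypotheses per step; ties are
    broken by lexicographic token order (smaller sequence wins). `model` must
    provide ``decode_step(prefix_ids, memory) -> distribution``.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    beams: list[tuple[list[int], float, bool]] = [([], 0.0, False)]
    for _ in range(max_len):
        candidates: list[tuple[list[int], float, bool]] = []
        for seq, logp, done in beams:
            if done:
                candidates.append((seq, logp, True))
                continue
            probs = model.decode_step(seq, memory).data
            logs = np.log(np.maximum(probs, 1e-300))
            for tok in range(len(probs)):
                candidates.append((seq + [tok], logp + float(logs[tok]),
                                   eos_id is not None and tok == eos_id))
        candidates.sort(key=lambda c: (-c[1], c[0]))
        beams = candidates[:width]
        if all(done for _, _, done in beams):
            break
    beams.sort(key=lambda c: (-c[1], c[0]))
    return beams[0][0]


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def cross_entropy(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer targets under `probs` rows."""
    probs = as_tensor(probs)
    targets = np.asarray(targets, dtype=int)
    onehot = np.zeros(probs.shape)
    np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
    picked = (probs * Tensor(onehot)).sum(axis=-1)
    if np.any(picked.data < 1e-12):
        warnings.warn("zero probability assigned to a target; clamped at 1e-12",
                      stacklevel=2)
    return -(picked.clamp_min(1e-12).log().mean())


def linguistic_loss(predictions: Tensor, targets) -> Tensor:
    """Token-level cross-entropy -sum_i log P(y_i | y_<i, X), mean-reduced."""
    return cross_entropy(predictions, np.asarray(targets, dtype=int))


def _pool_time(x: Tensor) -> Tensor:
    return as_tensor(x).mean(axis=-2)


def consistency_loss(f_audio: Tensor, c_agg: Tensor) -> Tensor:
    """Squared distance between time-pooled acoustic and aggregated states.

    Pooling over the time/position axes resolves the T x d vs N x d shape
    mismatch between the two representations.
    """
    diff = _pool_time(f_audio) - _pool_time(c_agg)
    per_item = (diff * diff).sum(axis=-1)
    return per_item.mean() if per_item.ndim else per_item


def total_loss(l_linguistic: Tensor, l_consistency: Tensor,
               lambda1: float, lambda2: float) -> LossBreakdown:
    """L = lambda1 * L_linguistic + lambda2 * L_consistency."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    l_ling = as_tensor(l_linguistic)
    l_cons = as_tensor(l_consistency)
    total = lambda1 * l_ling + lambda2 * l_cons
    return LossBreakdown(total=total,
                         terms={"linguistic": l_ling, "consistency": l_cons},
                         weights={"lambda1": lambda1, "lambda2": lambda2})
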