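"""Context-Adaptive Dual Attention (CADA).

Two attention stages over the encoded acoustic frames: *acoustic
self-attention* (ASA) computes softmax(H H^T / sqrt(d_h)) with no learned
projections — the literal form — followed by a residual layer-norm block;
*context-aware cross-attention* (CACA) attends from linguistic/query states
onto the acoustic frames after a gated context vector has been added to the
keys and values. A sigmoid gate C_dyn = sigma(W_c C + b_c) * C contracts the
context elementwise, so the context's influence is learned rather than fixed.

The L1 sparsity penalty on a row-stochastic attention matrix is identically
equal to the number of rows, so it cannot shape the attention distribution;
it is implemented literally (and excluded from the default objective), with
a mean row-entropy alternative that does reward peaked attention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alht import AttentionResult, LossBreakdown, _pool_time, cross_entropy
from .autodiff import Tensor, as_tensor, softmax
from .nn import LayerNorm, Linear, Module, dropout

__all__ = [
    "ContextBundle", "asa_attention", "sparsity_penalty", "AsaBlock",
    "ContextGate", "context_gate", "CacaAttention", "alignment_loss",
    "cada_total_loss",
]


@dataclass
class ContextBundle:
    """Raw context vector with its gate parameters and gated value."""

    context: np.ndarray
    c_dyn: np.ndarray
    gate_activation: np.ndarray


# --------------------------------------------------------------------------
# acoustic self-attention
# --------------------------------------------------------------------------

def asa_attention(h: Tensor, use_projections: bool = False,
                  proj_q: Linear | None = None, proj_k: Linear | None = None
                  ) -> tuple[AttentionResult, Tensor]:
    """Self-attention weights softmax(H H^T / sqrt(d_h)) and attended output.

    By default there are no learned query/key projections (the literal
    form); `use_projections` enables them for ablation comparisons.
    """
    h = as_tensor(h)
    d_h = h.shape[-1]
    if use_projections:
        if proj_q is None or proj_k is None:
            raise ValueError("use_projections requires proj_q and proj_k")
        q, k = proj_q(h), proj_k(h)
    else:
        q = k = h
    scores = (q @ k.transpose()) * (1.0 / np.sqrt(d_h))
    weights = softmax(scores, axis=-1)
    attended = weights @ h
    return AttentionResult(weights=weights.data, attended=attended.data,
                           scores=scores.data), attended


def sparsity_penalty(weights, mode: str = "l1"):
    """Attention-sparsity regularizer.

    ``l1``: entrywise L1 norm — for row-stochastic input this is exactly the
    number of rows, a constant, and is therefore excluded from the default
    training objective. ``entropy``: mean Shannon entropy of the rows, which
    is 0 at one-hot rows and log(T) at uniform rows and genuinely rewards
    peaked attention.
    """
    w = as_tensor(weights)
    if mode == "l1":
        # all entries are non-negative for softmax output
        flat = w.reshape(-1, w.shape[-1]) if w.ndim > 2 else w
        return flat.sum() * (1.0 / (np.prod(w.shape[:-2]) if w.ndim > 2 else 1.0))
    if mode == "entropy":
        ent = -(w * w.clamp_min(1e-300).log()).sum(axis=-1)
        return ent.mean()
    raise ValueError(f"unknown sparsity mode {mode!r}")


class AsaBlock(Module):
    """ASA with residual connection and layer normalization."""

    def __init__(self, d_model: int, use_projections: bool = False,
                 rng: np.random.Generator | None = None):
        self.use_projections = use_projections
        if use_projections:
            if rng is None:
                raise ValueError("projections require an init RNG")
            self.proj_q = Linear(d_model, d_model, rng)
            self.proj_k = Linear(d_model, d_model, rng)
        else:
            self.proj_q = self.proj_k = None
        self.norm = LayerNorm(d_model)

    def __call__(self, h: Tensor) -> tuple[Tensor, AttentionResult]:
        result, attended = asa_attention(h, use_projections=self.use_projections,
                                         proj_q=self.proj_q, proj_k=self.proj_k)
        return self.norm(attended + h), result


# --------------------------------------------------------------------------
# gated context
# --------------------------------------------------------------------------

def context_gate(c: Tensor, w_c: Tensor, b_c: Tensor,
                 rate: float = 0.0, rng: np.random.Generator | None = None) -> Tensor:
    """C_dyn = sigma(W_c C + b_c) * C (elementwise contraction of C).

    Train-time dropout, when enabled, is applied to the sigmoid activations
    rather than to C itself.
    """
    c = as_tensor(c)
    gate = (c @ as_tensor(w_c) + as_tensor(b_c)).sigmoid()
    gate = dropout(gate, rate, rng)
    return gate * c


class ContextGate(Module):
    """Learnable gate over a per-recording context vector projected to d."""

    def __init__(self, context_dim: int, d_model: int, rng: np.random.Generator,
                 rate: float = 0.0):
        # bias-free so that a zero context vector stays exactly zero
        self.proj = Linear(context_dim, d_model, rng, bias=False)
        self.w_c = Tensor(np.zeros((d_model, d_model)), requires_grad=True)
        self.b_c = Tensor(np.zeros(d_model), requires_grad=True)
        self.rate = rate

    def __call__(self, context, gated: bool = True,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Project raw context to model space; apply the gate unless bypassed."""
        c = self.proj(as_tensor(context))
        if not gated:
            return c
        return context_gate(c, self.w_c, self.b_c, rate=self.rate, rng=rng)


# --------------------------------------------------------------------------
# context-aware cross-attention
# --------------------------------------------------------------------------

class CacaAttention(Module):
    """Cross-attention from linguistic states G onto context-augmented frames.

    Q = Proj(G), K = Proj(H_ASA + C_dyn), V = H_ASA + C_dyn, followed by a
    residual layer-norm block. The context vector is broadcast-added across
    the T frames. When the number of query rows differs from T, the residual
    uses the time-pooled H_ASA (exact when the counts match).
    """

    def __init__(self, d_model: int, rng: np.random.Generator,
                 d_key: int | None = None, rate: float = 0.0):
        d_key = d_key or d_model
        self.proj_q = Linear(d_model, d_key, rng)
        self.proj_k = Linear(d_model, d_key, rng)
        self.norm = LayerNorm(d_model)
        self.d_key = d_key
        self.rate = rate

    def __call__(self, g: Tensor, h_asa: Tensor, c_dyn: Tensor | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, AttentionResult]:
        g = as_tensor(g)
        h_asa = as_tensor(h_asa)
        if c_dyn is None:
            v = h_asa
        else:
            c_dyn = as_tensor(c_dyn)
            if c_dyn.ndim < h_asa.ndim:       # broadcast vector across frames
                c_dyn = c_dyn.reshape(*c_dyn.shape[:-1], 1, c_dyn.shape[-1])
            v = h_asa + c_dyn
        q = self.proj_q(g)
        k = self.proj_k(v)
        scores = (q @ k.transpose()) * (1.0 / np.sqrt(self.d_key))
        weights = softmax(scores, axis=-1)
        attended = weights @ v
        result = AttentionResult(weights=weights.data, attended=attended.data,
                                 scores=scores.data)
        if g.shape[-2] == h_asa.shape[-2]:
            residual = h_asa
        else:
            pooled = h_asa.mean(axis=-2)
            residual = pooled.reshape(*pooled.shape[:-1], 1, pooled.shape[-1])
        out = self.norm(attended + residual)
        out = dropout(out, self.rate, rng)
        return out, result


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def alignment_loss(h_asa: Tensor, h_caca: Tensor) -> Tensor:
    """Squared distance between time-pooled ASA and CACA representations."""
    diff = _pool_time(h_asa) - _pool_time(h_caca)
    per_item = (diff * diff).sum(axis=-1)
    return per_item.mean() if per_item.ndim else per_item


def cada_total_loss(l_ce: Tensor, l_ca: Tensor, lambda1: float, lambda2: float,
                    sparsity: Tensor | float = 0.0,
                    sparsity_weight: float = 0.0) -> LossBreakdown:
    """L = lambda1 * L_CE + lambda2 * L_CA (+ sparsity_weight * R_ASA).

    The sparsity term defaults to weight 0 because the literal L1 penalty is
    constant for row-stochastic attention; pass the entropy-mode penalty with
    a positive weight to actually induce sparsity.
    """
    if lambda1 < 0 or lambda2 < 0 or sparsity_weight < 0:
        raise ValueError("loss weights must be non-negative")
    l_ce = as_tensor(l_ce)
    l_ca = as_tensor(l_ca)
    sp = as_tensor(sparsity)
    total = lambda1 * l_ce + lambda2 * l_ca
    if sparsity_weight > 0:
        total = total + sparsity_weight * sp
    return LossBreakdown(total=total,
                         terms={"cross_entropy": l_ce, "alignment": l_ca,
                                "sparsity": sp},
                         weights={"lambda1": lambda1, "lambda2": lambda2,
                                  "sparsity_weight": sparsity_weight})
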