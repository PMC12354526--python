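"""The full ALHT + CADA screening network.

Data flow for one batch of spectrogram windows (B, T, d_in) with per-window
context vectors (B, c):

1.  feature projection -> positional encoding -> learnable temporal
    convolution (noise suppression) -> frame re-weighting attention
    [bypassed when the acoustic-encoding ablation is active] ->
    transformer encoder stack -> H_La (B, T, d).
2.  acoustic self-attention block -> H_ASA.
3.  context gate -> C_dyn (raw projected context when the contextual-
    adaptation ablation is active).
4.  context-aware cross-attention from a bank of learned query tokens
    (the "linguistic states" of the binary screening task) -> H_CACA.
5.  temporal focus from H_CACA onto H_La, contextual aggregation with a
    global embedding S and a subject embedding E = Proj(context) -> C_agg,
    C_final; classifier head on C_final.

The training objective combines the classification cross-entropy, the
temporal-consistency term between H_La and C_agg, and the ASA/CACA
alignment term:  L = lambda1 * L_CE + lambda2 * (L_consistency + L_CA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alht import (ClassifierHead, ContextualAggregate, ConvNoiseSuppress,
                   CrossModalRefine, EncoderStack, FeatureProject,
                   FrameWeighting, LossBreakdown, ModelConfig, TemporalFocus,
                   TokenDecoder, consistency_loss, cross_entropy,
                   positional_encode, total_loss)
from .autodiff import Tensor, as_tensor, no_grad
from .cada import AsaBlock, CacaAttention, ContextGate, alignment_loss, cada_total_loss
from .nn import Linear, Module

__all__ = ["AblationFlags", "ScreeningNetwork", "soft_cross_entropy"]


@dataclass(frozen=True)
class AblationFlags:
    """Component removals mirroring the ablation-study rows.

    disable_aae_weighting: bypass the frame re-weighting attention.
    disable_ald_consistency: drop the temporal-consistency loss (lambda2 -> 0
        for that term).
    disable_dca_gating: bypass the context gate (the raw projected context is
        used, so the gate parameters cannot influence the output).
    """

    disable_aae_weighting: bool = False
    disable_ald_consistency: bool = False
    disable_dca_gating: bool = False


def soft_cross_entropy(probs: Tensor, soft_targets: np.ndarray) -> Tensor:
    """Cross-entropy against soft label distributions (mixup training)."""
    probs = as_tensor(probs)
    logp = probs.clamp_min(1e-12).log()
    per_item = -(logp * Tensor(np.asarray(soft_targets, dtype=np.float64))).sum(axis=-1)
    return per_item.mean()


class ScreeningNetwork(Module):
    """ALHT encoder + CADA attention + binary risk classifier."""

    def __init__(self, d_in: int, context_dim: int, config: ModelConfig,
                 seed: int = 0, ablation: AblationFlags | None = None,
                 max_positions: int = 512):
        config.validate()
        self.config = config
        self.ablation = ablation or AblationFlags()
        rng = np.random.default_rng(seed)
        d = config.d_model

        self.project = FeatureProject(d_in, d, rng)
        if config.positional_mode == "learned":
            self.pos_table = Tensor(rng.normal(0, 0.02, size=(max_positions, d)),
                                    requires_grad=True)
        else:
            self.pos_table = None
        self.conv = ConvNoiseSuppress(d, config.conv_width)
        self.frame_weight = FrameWeighting(d, rng)
        self.encoder = EncoderStack(config.n_encoder_layers, d, config.n_heads,
                                    config.d_ffn, config.dropout, rng)
        self.asa = AsaBlock(d)
        self.gate = ContextGate(context_dim, d, rng, rate=config.dropout)
        self.queries = Tensor(rng.normal(0, 0.5, size=(config.n_query_tokens, d)),
                              requires_grad=True)
        self.caca = CacaAttention(d, rng, rate=config.dropout)
        self.focus = TemporalFocus(d, rng)
        self.aggregate = ContextualAggregate(d, config.d_ffn, rng)
        self.refine = CrossModalRefine(d, rng)
        self.sentence_embed = Tensor(rng.normal(0, 0.5, size=(d,)), requires_grad=True)
        self.speaker_proj = Linear(context_dim, d, rng)
        self.head = ClassifierHead(d, rng)
        self.decoder = (TokenDecoder(config, rng)
                        if config.head_mode == "token_sequence" else None)

    # -- forward -------------------------------------------------------------
    def _positional(self, x: Tensor) -> Tensor:
        if self.pos_table is not None:
            t = x.shape[-2]
            if t > self.pos_table.shape[0]:
                raise ValueError("sequence longer than the learned position table")
            sel = Tensor(np.eye(self.pos_table.shape[0])[:t])
            return x + sel @ self.pos_table
        return positional_encode(x, mode=self.config.positional_mode)

    def forward(self, features: np.ndarray, contexts: np.ndarray,
                rng: np.random.Generator | None = None) -> dict:
        """Run the network; `rng` enables train-time dropout."""
        x = self.project(features)
        x = self._positional(x)
        x = self.conv(x)
        aae_attention = None
        if not self.ablation.disable_aae_weighting:
            x, aae_attention = self.frame_weight(x)
        h_la = self.encoder(x, rng=rng)
        h_asa, asa_result = self.asa(h_la)
        c_dyn = self.gate(contexts, gated=not self.ablation.disable_dca_gating, rng=rng)
        h_caca, caca_result = self.caca(self.queries, h_asa, c_dyn, rng=rng)
        focus_result, c_focus = self.focus(h_caca, h_la)
        e = self.speaker_proj(as_tensor(contexts))
        if e.ndim >= 2:
            e = e.reshape(*e.shape[:-1], 1, e.shape[-1])
        c_agg, c_final = self.aggregate(c_focus, self.sentence_embed, e)
        probs = self.head(c_final)
        return {"probs": probs, "h_la": h_la, "h_asa": h_asa, "h_caca": h_caca,
                "c_agg": c_agg, "c_final": c_final, "c_dyn": c_dyn,
                "attention": {"frame_weighting": aae_attention, "asa": asa_result,
                              "caca": caca_result, "temporal_focus": focus_result}}

    # -- objective -----------------------------------------------------------
    def compute_loss(self, out: dict, labels: np.ndarray,
                     soft_labels: np.ndarray | None = None) -> LossBreakdown:
        """Composite objective from a forward pass.

        `soft_labels` (B, 2), when given, replaces the hard labels in the
        cross-entropy term (mixup batches).
        """
        cfg = self.config
        if soft_labels is not None:
            l_ce = soft_cross_entropy(out["probs"], soft_labels)
        else:
            l_ce = cross_entropy(out["probs"], labels)
        if self.ablation.disable_ald_consistency:
            l_cons = Tensor(0.0)
        else:
            l_cons = consistency_loss(out["h_la"], out["c_agg"])
        alht_part = total_loss(l_ce, l_cons, cfg.lambda1, cfg.lambda2)
        l_ca = alignment_loss(out["h_asa"], out["h_caca"])
        cada_part = cada_total_loss(l_ce, l_ca, 0.0, cfg.lambda2)
        total = alht_part.total + cada_part.total
        return LossBreakdown(
            total=total,
            terms={"cross_entropy": l_ce, "consistency": l_cons, "alignment": l_ca},
            weights={"lambda1": cfg.lambda1, "lambda2": cfg.lambda2})

    # -- inference -----------------------------------------------------------
    def predict(self, features: np.ndarray, contexts: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        """Window-level (labels, high-risk scores) without building a graph."""
        with no_grad():
            out = self.forward(features, contexts, rng=None)
        probs = out["probs"].data
        return probs.argmax(axis=-1), probs[..., 1]
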