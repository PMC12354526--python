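"""Optimization protocol: AdamW, cosine annealing, early stopping, replicates.

Training is fully seeded: a (config, seed) pair reproduces checkpoints and
metrics bit-identically. Replicate runs use seeds base_seed + 0 .. n_runs-1
and are aggregated as mean +/- sample standard deviation by the evaluation
module. The ablation harness retrains the network with each component
removal and reports the same metric table structure for every variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .alht import ModelConfig
from .autodiff import Tensor, no_grad
from .evaluation import MetricsReport, aggregate_runs, evaluate_windows
from .network import AblationFlags, ScreeningNetwork
from .preprocessing import FeatureMatrix, WindowDataset, apply_masking, mixup

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainState", "AdamW", "lr_at_epoch", "should_stop",
    "train_once", "run_replicates", "ablation_suite", "split_subjects",
    "ABLATION_VARIANTS",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 64
    patience: int = 10
    min_delta: float = 1e-4
    n_runs: int = 3
    base_seed: int = 0
    mask_time_width: int = 4
    mask_freq_width: int = 4
    mask_n: int = 1
    mixup_alpha: float = 0.0   # 0 disables mixup
    eta_min: float = 0.0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1 or self.n_runs < 1:
            raise ValueError("patience and n_runs must be >= 1")


@dataclass
class TrainState:
    """Mutable bookkeeping for one training run."""

    epoch: int = 0
    best_val_loss: float = np.inf
    best_epoch: int = -1
    epochs_without_improvement: int = 0
    history: list[dict] = field(default_factory=list)

    def update_validation(self, val_loss: float, min_delta: float) -> bool:
        """Record a validation result; returns True if it improved."""
        if val_loss <= self.best_val_loss - min_delta:
            self.best_val_loss = val_loss
            self.best_epoch = self.epoch
            self.epochs_without_improvement = 0
            return True
        self.epochs_without_improvement += 1
        return False


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Cosine annealing: eta(e) = eta_min + (eta0 - eta_min)/2 (1 + cos(pi e/E))."""
    if not 0 <= epoch <= config.max_epochs:
        raise ValueError("epoch out of range")
    eta0, eta_min = config.learning_rate, config.eta_min
    return eta_min + 0.5 * (eta0 - eta_min) * (1 + np.cos(np.pi * epoch / config.max_epochs))


def should_stop(state: TrainState, config: TrainConfig) -> bool:
    """True iff validation loss has not improved by min_delta for `patience` epochs."""
    return state.epochs_without_improvement >= config.patience


class AdamW:
    """Decoupled weight-decay Adam (bias-corrected moments)."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)


def split_subjects(subject_labels: dict[str, int], val_fraction: float,
                   seed: int) -> tuple[set[str], set[str]]:
    """Stratified subject-level split; no subject straddles the splits."""
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    val: set[str] = set()
    for cls in (0, 1):
        ids = sorted(s for s, lab in subject_labels.items() if lab == cls)
        rng.shuffle(ids)
        n_val = max(1, round(val_fraction * len(ids))) if ids else 0
        val.update(ids[:n_val])
        train.update(ids[n_val:])
    if not train or not val:
        raise ValueError("split produced an empty side; need more subjects")
    return train, val


def _augment_batch(feats: np.ndarray, labels: np.ndarray, config: TrainConfig,
                   frame_rate: float, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray | None]:
    """Train-time masking (and optional mixup); returns (features, soft labels)."""
    out = np.empty_like(feats)
    for i in range(feats.shape[0]):
        fm = FeatureMatrix(values=feats[i], frame_rate=frame_rate)
        if config.mask_time_width > 0:
            fm = apply_masking(fm, "time", config.mask_time_width, config.mask_n, rng)
        if config.mask_freq_width > 0:
            fm = apply_masking(fm, "frequency", config.mask_freq_width, config.mask_n, rng)
        out[i] = fm.values
    if config.mixup_alpha <= 0:
        return out, None
    lam = float(rng.beta(config.mixup_alpha, config.mixup_alpha))
    perm = rng.permutation(feats.shape[0])
    onehot = np.eye(2)[labels]
    mixed_f, mixed_y = mixup((out, onehot), (out[perm], onehot[perm]), lam)
    return mixed_f, mixed_y


def _validation_pass(model: ScreeningNetwork, dataset: WindowDataset,
                     batch_size: int) -> tuple[float, float]:
    """(validation loss, validation accuracy), deterministic eval path."""
    losses, hits, n = [], 0, 0
    with no_grad():
        for start in range(0, dataset.n_windows, batch_size):
            sl = slice(start, start + batch_size)
            out = model.forward(dataset.features[sl], dataset.contexts[sl], rng=None)
            breakdown = model.compute_loss(out, dataset.labels[sl])
            bsz = out["probs"].shape[0]
            losses.append(breakdown.value() * bsz)
            hits += int((out["probs"].data.argmax(axis=-1) == dataset.labels[sl]).sum())
            n += bsz
    return sum(losses) / n, hits / n


def train_once(model_config: ModelConfig, train_ds: WindowDataset,
               val_ds: WindowDataset, train_config: TrainConfig, seed: int,
               ablation: AblationFlags | None = None
               ) -> tuple[dict, list[dict]]:
    """One seeded training run; returns (checkpoint, per-epoch history).

    The checkpoint holds the parameters at the best validation loss, the
    configurations and the seed, so the run is fully reproducible.
    """
    train_config.validate()
    model_config.validate()
    if train_ds.n_windows == 0 or val_ds.n_windows == 0:
        raise ValueError("train and validation splits must be non-empty")
    overlap = set(train_ds.subject_ids) & set(val_ds.subject_ids)
    if overlap:
        raise ValueError(f"subjects straddle the train/val split: {sorted(overlap)}")

    d_in = train_ds.features.shape[-1]
    context_dim = train_ds.contexts.shape[-1]
    model = ScreeningNetwork(d_in, context_dim, model_config, seed=seed,
                             ablation=ablation)
    opt = AdamW(model.parameters(), lr=train_config.learning_rate,
                weight_decay=train_config.weight_decay)
    data_rng = np.random.default_rng(seed + 1)
    dropout_rng = np.random.default_rng(seed + 2)

    state = TrainState()
    best_params = model.state_dict()
    for epoch in range(train_config.max_epochs):
        state.epoch = epoch
        opt.lr = lr_at_epoch(epoch, train_config)
        order = data_rng.permutation(train_ds.n_windows)
        epoch_terms: dict[str, float] = {}
        n_seen = 0
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            feats, soft = _augment_batch(train_ds.features[idx], train_ds.labels[idx],
                                         train_config, train_ds.frame_rate, data_rng)
            out = model.forward(feats, train_ds.contexts[idx], rng=dropout_rng)
            breakdown = model.compute_loss(out, train_ds.labels[idx], soft_labels=soft)
            opt.zero_grad()
            breakdown.total.backward()
            opt.step()
            bsz = len(idx)
            n_seen += bsz
            for name, term in breakdown.terms.items():
                epoch_terms[name] = epoch_terms.get(name, 0.0) + float(term.data) * bsz
            epoch_terms["total"] = epoch_terms.get("total", 0.0) + breakdown.value() * bsz
        val_loss, val_acc = _validation_pass(model, val_ds, train_config.batch_size)
        improved = state.update_validation(val_loss, train_config.min_delta)
        if improved:
            best_params = model.state_dict()
        record = {name: total / n_seen for name, total in epoch_terms.items()}
        record.update({"epoch": epoch, "lr": opt.lr, "val_loss": val_loss,
                       "val_accuracy": val_acc})
        state.history.append(record)
        logger.info("epoch %d: train %.4f, val %.4f (acc %.3f)",
                    epoch, record["total"], val_loss, val_acc)
        if should_stop(state, train_config):
            logger.info("early stopping at epoch %d (best %d)", epoch, state.best_epoch)
            break

    checkpoint = {"state_dict": best_params, "model_config": model_config,
                  "train_config": train_config, "seed": seed,
                  "ablation": ablation or AblationFlags(),
                  "best_epoch": state.best_epoch,
                  "best_val_loss": state.best_val_loss,
                  "d_in": d_in, "context_dim": context_dim}
    return checkpoint, state.history


def model_from_checkpoint(checkpoint: dict) -> ScreeningNetwork:
    model = ScreeningNetwork(checkpoint["d_in"], checkpoint["context_dim"],
                             checkpoint["model_config"], seed=checkpoint["seed"],
                             ablation=checkpoint.get("ablation") or AblationFlags())
    model.load_state_dict(checkpoint["state_dict"])
    return model


def run_replicates(model_config: ModelConfig, train_ds: WindowDataset,
                   val_ds: WindowDataset, train_config: TrainConfig,
                   ablation: AblationFlags | None = None
                   ) -> tuple[list[dict], list[MetricsReport], MetricsReport]:
    """n_runs independent seeded runs; aggregate mean +/- sample std."""
    checkpoints, reports = [], []
    for run in range(train_config.n_runs):
        seed = train_config.base_seed + run
        ckpt, history = train_once(model_config, train_ds, val_ds, train_config,
                                   seed, ablation=ablation)
        ckpt["history"] = history
        model = model_from_checkpoint(ckpt)
        labels, scores = model.predict(val_ds.features, val_ds.contexts)
        reports.append(evaluate_windows(val_ds.labels, labels, scores))
        checkpoints.append(ckpt)
    return checkpoints, reports, aggregate_runs(reports)


ABLATION_VARIANTS: dict[str, AblationFlags] = {
    "full": AblationFlags(),
    "wo_advanced_acoustic_encoding": AblationFlags(disable_aae_weighting=True),
    "wo_adaptive_linguistic_decoding": AblationFlags(disable_ald_consistency=True),
    "wo_dynamic_contextual_adaptation": AblationFlags(disable_dca_gating=True),
}


def ablation_suite(model_config: ModelConfig, train_ds: WindowDataset,
                   val_ds: WindowDataset, train_config: TrainConfig
                   ) -> dict[str, MetricsReport]:
    """Retrain with each component removed; one aggregated report per variant.

    Rows: the full model plus one row per disabled component (frame
    re-weighting, consistency loss, context gating), mirroring the standard
    ablation table structure.
    """
    results: dict[str, MetricsReport] = {}
    for name, flags in ABLATION_VARIANTS.items():
        logger.info("ablation variant: %s", name)
        _, _, aggregate = run_replicates(model_config, train_ds, val_ds,
                                         train_config, ablation=flags)
        results[name] = aggregate
    return results
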