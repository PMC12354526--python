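"""EEG signal pipeline: bandpass, standardization, windowing, CSP, STFT.

Stage order is fixed: bandpass filter -> per-channel standardization ->
fixed-length windowing -> CSP spatial filtering -> STFT log-spectrogram ->
feature standardization (statistics fit on the training split only). The
masking and mixup augmentations are train-time only and never enter the
evaluation path; `build_features` records the stage sequence in a manifest
so that downstream audits can assert the ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal as sps

from .cohort import ConfigurationError, LabeledRecording

logger = logging.getLogger(__name__)

__all__ = [
    "Window", "FeatureMatrix", "SpatialFilterBank", "PreprocessConfig",
    "WindowDataset", "bandpass_filter", "standardize_channels",
    "segment_windows", "csp_fit", "csp_apply", "csp_from_covariances",
    "stft_spectrogram", "stft_frames", "apply_masking", "mixup",
    "remove_artifacts", "welch_band_power", "FeatureScaler", "build_features",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Window:
    """A fixed-length segment inheriting the recording's label and context."""

    signal: np.ndarray          # (channels, samples)
    sampling_rate: float
    label: int
    context: np.ndarray
    subject_id: str
    start_time: float


@dataclass
class FeatureMatrix:
    """Time-major feature array (T frames x d features)."""

    values: np.ndarray
    frame_rate: float
    axis_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with T >= 1, d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass
class SpatialFilterBank:
    """CSP filters ordered by descending generalized eigenvalue.

    Each filter w satisfies w^T (S1 + S2) w = 1 under the eigh(S1, S1+S2)
    normalization, and its eigenvalue in (0, 1) is the fraction of the pooled
    variance explained by class 1 along w.
    """

    filters: np.ndarray         # (channels, n_filters)
    eigenvalues: np.ndarray     # (n_filters,) descending
    fitted_on: str = ""


# --------------------------------------------------------------------------
# signal-level stages
# --------------------------------------------------------------------------

def bandpass_filter(recording: LabeledRecording, low: float = 0.5,
                    high: float = 45.0) -> LabeledRecording:
    """Zero-phase 4th-order Butterworth bandpass, applied forward-backward."""
    nyq = recording.sampling_rate / 2.0
    if not 0 < low < high:
        raise ConfigurationError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ConfigurationError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=recording.sampling_rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    return LabeledRecording(signal=filtered, sampling_rate=recording.sampling_rate,
                            label=recording.label, context=recording.context,
                            subject_id=recording.subject_id,
                            stimulus_onsets=recording.stimulus_onsets)


def standardize_channels(signal: np.ndarray) -> np.ndarray:
    """Per-channel zero mean, unit (population) variance."""
    signal = np.asarray(signal, dtype=np.float64)
    mean = signal.mean(axis=1, keepdims=True)
    sd = signal.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant channel(s) cannot be standardized: {flat.tolist()}")
    return (signal - mean) / sd


def segment_windows(recording: LabeledRecording, window: float = 60.0,
                    overlap: float = 0.5) -> list[Window]:
    """Fixed-length windows starting at k*window*(1-overlap) seconds.

    Incomplete trailing windows are dropped. Each window inherits the
    recording's label, context and subject id (segment-level labels).
    """
    if not 0 <= overlap < 1:
        raise ConfigurationError(f"overlap must lie in [0, 1), got {overlap}")
    fs = recording.sampling_rate
    win_samples = round(window * fs)
    step_samples = round(window * (1 - overlap) * fs)
    if step_samples < 1:
        raise ConfigurationError("window step is below one sample")
    n = recording.n_samples
    if n < win_samples:
        warnings.warn(f"recording {recording.subject_id} shorter than one window; "
                      "returning no segments", stacklevel=2)
        return []
    windows = []
    start = 0
    while start + win_samples <= n:
        windows.append(Window(signal=recording.signal[:, start:start + win_samples].copy(),
                              sampling_rate=fs, label=recording.label,
                              context=recording.context, subject_id=recording.subject_id,
                              start_time=start / fs))
        start += step_samples
    return windows


# --------------------------------------------------------------------------
# CSP
# --------------------------------------------------------------------------

def _shrunk(cov: np.ndarray, shrinkage: float) -> np.ndarray:
    dim = cov.shape[0]
    return cov + shrinkage * np.trace(cov) / dim * np.eye(dim)


def csp_from_covariances(cov1: np.ndarray, cov2: np.ndarray, m: int = 3,
                         shrinkage: float = 1e-6) -> SpatialFilterBank:
    """CSP filters from two class covariances.

    Solves the generalized eigenproblem S1 w = lambda (S1 + S2) w after
    shrinkage regularization (shrinkage * trace/dim added to each class
    covariance) and keeps `m` filters from each spectral end.
    """
    s1 = _shrunk(np.asarray(cov1, dtype=np.float64), shrinkage)
    s2 = _shrunk(np.asarray(cov2, dtype=np.float64), shrinkage)
    evals, evecs = linalg.eigh(s1, s1 + s2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    dim = evecs.shape[1]
    if 2 * m >= dim:
        keep = np.arange(dim)
    else:
        keep = np.concatenate([np.arange(m), np.arange(dim - m, dim)])
    return SpatialFilterBank(filters=evecs[:, keep], eigenvalues=evals[keep])


def _window_covariance(w: Window) -> np.ndarray:
    x = w.signal
    cov = x @ x.T / x.shape[1]
    return cov / np.trace(cov)


def csp_fit(windows: list[Window], m: int = 3, shrinkage: float = 1e-6) -> SpatialFilterBank:
    """Fit CSP on labeled windows (trace-normalized per-window covariances)."""
    labels = {w.label for w in windows}
    if labels != {0, 1}:
        raise ValueError("CSP requires windows from both classes")
    n_ch = windows[0].signal.shape[0]
    for w in windows:
        if w.signal.shape[1] < n_ch:
            raise ValueError("each window needs at least `channels` samples")
    cov1 = np.mean([_window_covariance(w) for w in windows if w.label == 1], axis=0)
    cov0 = np.mean([_window_covariance(w) for w in windows if w.label == 0], axis=0)
    bank = csp_from_covariances(cov1, cov0, m=m, shrinkage=shrinkage)
    bank.fitted_on = "training-split window labels (1 = high risk vs 0 = low risk)"
    return bank


def csp_apply(window, bank: SpatialFilterBank):
    """Project a window (or raw array) onto the CSP filters: filters^T @ x."""
    x = window.signal if isinstance(window, Window) else np.asarray(window, dtype=np.float64)
    if x.shape[0] != bank.filters.shape[0]:
        raise ValueError(f"channel mismatch: window has {x.shape[0]}, "
                         f"bank expects {bank.filters.shape[0]}")
    out = bank.filters.T @ x
    if isinstance(window, Window):
        return Window(signal=out, sampling_rate=window.sampling_rate, label=window.label,
                      context=window.context, subject_id=window.subject_id,
                      start_time=window.start_time)
    return out


# --------------------------------------------------------------------------
# STFT features
# --------------------------------------------------------------------------

def stft_frames(x: np.ndarray, fs: float, stft_window: float = 1.0,
                hop: float = 0.5) -> tuple[np.ndarray, np.ndarray, float]:
    """One-sided STFT magnitudes of valid (fully contained) Hann frames.

    Returns (mags, freqs, frame_rate) with mags shaped
    (n_frames, channels, n_bins). No padding is applied, so every frame's
    energy obeys Parseval's identity against the windowed segment.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    nperseg = round(stft_window * fs)
    hop_samples = round(hop * nperseg)
    if hop_samples < 1:
        raise ConfigurationError("hop must be positive")
    if nperseg > x.shape[1]:
        raise ConfigurationError("stft_window longer than the signal")
    win = sps.get_window("hann", nperseg)
    frames = np.lib.stride_tricks.sliding_window_view(x, nperseg, axis=1)[:, ::hop_samples]
    spec = np.fft.rfft(frames * win, axis=-1)          # (channels, frames, bins)
    mags = np.abs(spec).transpose(1, 0, 2)             # (frames, channels, bins)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return mags, freqs, fs / hop_samples


def stft_spectrogram(window, stft_window: float = 1.0, hop: float = 0.5,
                     floor: float = 1e-10) -> FeatureMatrix:
    """Log-magnitude spectrogram stacked into the T x d layout.

    d = channels * frequency_bins, channel-major; magnitudes are floored at
    `floor` before the natural log.
    """
    if isinstance(window, Window):
        x, fs = window.signal, window.sampling_rate
    else:
        raise TypeError("stft_spectrogram expects a Window")
    mags, freqs, frame_rate = stft_frames(x, fs, stft_window=stft_window, hop=hop)
    n_frames, n_ch, n_bins = mags.shape
    values = np.log(np.maximum(mags, floor)).reshape(n_frames, n_ch * n_bins)
    meta = {"channels": n_ch, "freqs": freqs, "layout": "channel-major (ch * bins + bin)"}
    return FeatureMatrix(values=values, frame_rate=frame_rate, axis_meta=meta)


# --------------------------------------------------------------------------
# augmentations (train-time only)
# --------------------------------------------------------------------------

def apply_masking(features: FeatureMatrix, axis: str, max_width: int,
                  n_masks: int, rng: np.random.Generator) -> FeatureMatrix:
    """Mask `n_masks` contiguous spans on the time or frequency axis.

    Masked entries are replaced by the per-feature-column mean of the input,
    which keeps batch statistics stable. `max_width` = 0 is a no-op.
    """
    if axis not in ("time", "frequency"):
        raise ValueError("axis must be 'time' or 'frequency'")
    values = features.values.copy()
    t, d = values.shape
    length = t if axis == "time" else d
    if max_width >= length:
        raise ValueError(f"max_width {max_width} must be below axis length {length}")
    col_means = features.values.mean(axis=0)
    for _ in range(n_masks):
        width = int(rng.integers(0, max_width + 1))
        if width == 0:
            continue
        start = int(rng.integers(0, length - width + 1))
        if axis == "time":
            values[start:start + width, :] = col_means[None, :]
        else:
            values[:, start:start + width] = col_means[None, start:start + width]
    return FeatureMatrix(values=values, frame_rate=features.frame_rate,
                         axis_meta=dict(features.axis_meta))


def mixup(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray],
          lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Convex combination lam*a + (1-lam)*b of features and one-hot labels."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    fa, ya = a
    fb, yb = b
    if np.shape(fa) != np.shape(fb) or np.shape(ya) != np.shape(yb):
        raise ValueError("mixup operands must have matching shapes")
    return (lam * np.asarray(fa) + (1 - lam) * np.asarray(fb),
            lam * np.asarray(ya) + (1 - lam) * np.asarray(yb))


def remove_artifacts(recording: LabeledRecording) -> LabeledRecording:
    """Ocular/muscular artifact-removal hook.

    Identity: synthetic cohorts carry no ocular or muscle artifacts, so the
    hook exists only to keep the stage slot in the pipeline for real data.
    """
    logger.info("artifact removal hook is identity (no artifact model configured)")
    return recording


# --------------------------------------------------------------------------
# spectral utilities
# --------------------------------------------------------------------------

def welch_band_power(signal_arr: np.ndarray, fs: float,
                     band: tuple[float, float]) -> float:
    """Mean band power (Welch PSD integrated over `band`, averaged over channels)."""
    x = np.atleast_2d(np.asarray(signal_arr, dtype=np.float64))
    nperseg = min(x.shape[1], int(4 * fs))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg, axis=1)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[:, sel], freqs[sel], axis=1).mean())


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    low: float = 0.5
    high: float = 45.0
    window: float = 60.0
    overlap: float = 0.5
    csp_filters_per_end: int = 3
    csp_shrinkage: float = 1e-6
    stft_window: float = 1.0
    stft_hop: float = 0.5
    standardize_features: bool = True


class FeatureScaler:
    """Per-feature-column standardization, fit on training frames only."""

    def __init__(self) -> None:
        self.mean: np.ndarray | None = None
        self.sd: np.ndarray | None = None

    def fit(self, stacked: np.ndarray) -> "FeatureScaler":
        frames = stacked.reshape(-1, stacked.shape[-1])
        self.mean = frames.mean(axis=0)
        sd = frames.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, stacked: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler not fitted")
        return (stacked - self.mean) / self.sd


@dataclass
class WindowDataset:
    """Stacked window features plus labels, contexts and provenance."""

    features: np.ndarray        # (n_windows, T, d)
    labels: np.ndarray          # (n_windows,)
    contexts: np.ndarray        # (n_windows, context_dim)
    subject_ids: list[str]
    frame_rate: float
    manifest: dict = field(default_factory=dict)

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        idx = np.flatnonzero(mask)
        return WindowDataset(features=self.features[idx], labels=self.labels[idx],
                             contexts=self.contexts[idx],
                             subject_ids=[self.subject_ids[i] for i in idx],
                             frame_rate=self.frame_rate, manifest=dict(self.manifest))

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


def build_features(recordings: list[LabeledRecording], config: PreprocessConfig,
                   train_subjects: set[str]) -> tuple[WindowDataset, WindowDataset]:
    """Run the full pipeline and return (train, eval) window datasets.

    CSP filters and feature-standardization statistics are fit on the
    training subjects only and frozen for the evaluation split. The returned
    manifests record the executed stage sequence and parameters.
    """
    stages: list[dict] = []
    processed: list[LabeledRecording] = []
    for rec in recordings:
        rec = remove_artifacts(rec)
        rec = bandpass_filter(rec, low=config.low, high=config.high)
        rec = LabeledRecording(signal=standardize_channels(rec.signal),
                               sampling_rate=rec.sampling_rate, label=rec.label,
                               context=rec.context, subject_id=rec.subject_id,
                               stimulus_onsets=rec.stimulus_onsets)
        processed.append(rec)
    stages.append({"stage": "artifact_removal", "mode": "identity"})
    stages.append({"stage": "bandpass_filter", "low": config.low, "high": config.high,
                   "order": 4, "zero_phase": True})
    stages.append({"stage": "standardize_channels"})

    windows: list[Window] = []
    for rec in processed:
        windows.extend(segment_windows(rec, window=config.window, overlap=config.overlap))
    stages.append({"stage": "segment_windows", "window_s": config.window,
                   "overlap": config.overlap})
    if not windows:
        raise ValueError("no windows produced; recordings shorter than one window")

    train_mask = np.array([w.subject_id in train_subjects for w in windows])
    if not train_mask.any() or train_mask.all():
        raise ValueError("train/eval split must be non-trivial at the subject level")
    bank = csp_fit([w for w, m in zip(windows, train_mask) if m],
                   m=config.csp_filters_per_end, shrinkage=config.csp_shrinkage)
    windows = [csp_apply(w, bank) for w in windows]
    stages.append({"stage": "csp", "filters_per_end": config.csp_filters_per_end,
                   "n_filters": bank.filters.shape[1], "fit_on": "train split"})

    feats = [stft_spectrogram(w, stft_window=config.stft_window, hop=config.stft_hop)
             for w in windows]
    stages.append({"stage": "stft_spectrogram", "window_s": config.stft_window,
                   "hop": config.stft_hop, "log_floor": 1e-10})
    stacked = np.stack([f.values for f in feats])

    if config.standardize_features:
        scaler = FeatureScaler().fit(stacked[train_mask])
        stacked = scaler.transform(stacked)
        stages.append({"stage": "feature_standardize", "fit_on": "train split"})

    manifest = {"stages": stages,
                "augmentation": {"masking": "train-only", "mixup": "train-only"},
                "frame_rate": feats[0].frame_rate}
    labels = np.array([w.label for w in windows])
    contexts = np.stack([w.context for w in windows])
    ids = [w.subject_id for w in windows]
    full = WindowDataset(features=stacked, labels=labels, contexts=contexts,
                         subject_ids=ids, frame_rate=feats[0].frame_rate,
                         manifest=manifest)
    return full.subset(train_mask), full.subset(~train_mask)
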