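"""Seeded synthetic EEG cohorts with class-dependent spectral structure.

High-risk recordings carry suppressed alpha-band (8-12 Hz) power, elevated
theta-band (4-7 Hz) power and, optionally, an attenuated stimulus-locked
negative deflection near 400 ms — the qualitative EEG signatures associated
with OSA-related cognitive strain (cognitive fatigue, working-memory
overload, impaired semantic processing). The generator exists so that every
downstream stage (preprocessing, model, training, evaluation) is testable
end to end without access to clinical recordings.

Signal model per channel: Gaussian broadband noise plus one narrowband
oscillation per configured band (random frequency within the band, random
phase), plus the optional event-related deflection. Class membership only
rescales the band amplitudes and the deflection depth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CohortConfig", "LabeledRecording", "simulate_recording", "simulate_cohort",
    "stop_bang_label", "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised for invalid cohort or pipeline configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic screening cohort.

    Amplitudes are in arbitrary signal units (interpretable as microvolts).
    The rest-state convention is high alpha (amplitude ``alpha_amp``) and low
    theta (``theta_amp``); the high-risk class multiplies those by
    ``risk_alpha_factor`` (< 1, suppression) and ``risk_theta_factor``
    (> 1, elevation).
    """

    n_subjects: int = 30
    channels: int = 8
    sampling_rate: float = 128.0
    duration: float = 300.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    theta_band: tuple[float, float] = (4.0, 7.0)
    alpha_amp: float = 1.0
    theta_amp: float = 0.5
    risk_alpha_factor: float = 0.5
    risk_theta_factor: float = 1.8
    noise_sd: float = 1.0
    erp_enabled: bool = True
    erp_latency: float = 0.4
    erp_attenuation: float = 0.4
    erp_amp: float = 1.5
    stimulus_interval: float = 5.0
    context_dim: int = 4
    class_balance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name, band in (("alpha_band", self.alpha_band), ("theta_band", self.theta_band)):
            lo, hi = band
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} edges must satisfy 0 < low <= high, got {band}")
            if self.sampling_rate <= 2 * hi:
                raise ConfigurationError(
                    f"sampling_rate {self.sampling_rate} violates Nyquist for {name} {band}")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if not 0 < self.risk_alpha_factor < 1:
            raise ConfigurationError("risk_alpha_factor must lie in (0, 1)")
        if self.risk_theta_factor <= 1:
            raise ConfigurationError("risk_theta_factor must exceed 1")
        if not 0 < self.class_balance < 1:
            raise ConfigurationError("class_balance must lie in (0, 1)")
        if self.context_dim < 1:
            raise ConfigurationError("context_dim must be >= 1")
        if self.channels < 1 or self.n_subjects < 0:
            raise ConfigurationError("channels and n_subjects must be positive")


@dataclass
class LabeledRecording:
    """One subject's multichannel recording with its risk label and context."""

    signal: np.ndarray          # (channels, samples)
    sampling_rate: float
    label: int                  # 0 = low risk, 1 = high risk
    context: np.ndarray         # (context_dim,)
    subject_id: str
    stimulus_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.context = np.asarray(self.context, dtype=np.float64)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not np.all(np.isfinite(self.context)):
            raise ValueError("context vector must be finite")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _band_oscillation(rng: np.random.Generator, t: np.ndarray, band: tuple[float, float],
                      amp: float, channels: int) -> np.ndarray:
    """Narrowband component: per-channel random frequency in band, random phase."""
    lo, hi = band
    freqs = rng.uniform(lo, hi, size=channels)
    phases = rng.uniform(0, 2 * np.pi, size=channels)
    # mild per-channel amplitude jitter keeps channels non-identical
    amps = amp * rng.uniform(0.85, 1.15, size=channels)
    return amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])


def _erp_component(t: np.ndarray, onsets: np.ndarray, latency: float,
                   amp: float, width: float = 0.05) -> np.ndarray:
    """Gaussian-windowed negative deflection `latency` seconds after each onset."""
    wave = np.zeros_like(t)
    for onset in onsets:
        center = onset + latency
        wave -= amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return wave


def simulate_recording(config: CohortConfig, label: int,
                       rng: np.random.Generator,
                       subject_id: str = "S000") -> LabeledRecording:
    """Simulate one subject's recording under the configured signal model."""
    config.validate()
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    n = round(config.duration * config.sampling_rate)
    t = np.arange(n) / config.sampling_rate

    alpha_amp = config.alpha_amp * (config.risk_alpha_factor if label == 1 else 1.0)
    theta_amp = config.theta_amp * (config.risk_theta_factor if label == 1 else 1.0)

    signal = config.noise_sd * rng.standard_normal((config.channels, n))
    if alpha_amp > 0:
        signal += _band_oscillation(rng, t, config.alpha_band, alpha_amp, config.channels)
    if theta_amp > 0:
        signal += _band_oscillation(rng, t, config.theta_band, theta_amp, config.channels)

    if config.erp_enabled:
        onsets = np.arange(1.0, config.duration - config.erp_latency - 0.5,
                           config.stimulus_interval)
        erp_amp = config.erp_amp * (config.erp_attenuation if label == 1 else 1.0)
        signal += _erp_component(t, onsets, config.erp_latency, erp_amp)[None, :]
    else:
        onsets = np.empty(0)

    # Context: label-independent nuisance draws plus a noise-profile scalar.
    nuisance = rng.standard_normal(max(config.context_dim - 1, 0))
    noise_profile = config.noise_sd * (1.0 + 0.1 * rng.standard_normal())
    context = np.concatenate([nuisance, [noise_profile]])[: config.context_dim]

    return LabeledRecording(signal=signal, sampling_rate=config.sampling_rate,
                            label=label, context=context, subject_id=subject_id,
                            stimulus_onsets=onsets)


def _subject_seed(seed: int, subject_index: int) -> int:
    """Stable per-subject sub-seed from (cohort seed, subject index)."""
    digest = hashlib.sha256(f"{seed}:{subject_index}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def simulate_cohort(config: CohortConfig) -> list[LabeledRecording]:
    """Simulate the full cohort with deterministic per-subject sub-seeding.

    floor(class_balance * n_subjects) subjects are high-risk; each subject's
    signal depends only on (config, subject index, label), so permuting
    subject order leaves per-subject signals unchanged.
    """
    config.validate()
    if config.n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects (both classes required)")
    n_high = int(np.floor(config.class_balance * config.n_subjects))
    recordings = []
    for idx in range(config.n_subjects):
        label = 1 if idx < n_high else 0
        rng = np.random.default_rng(_subject_seed(config.seed, idx))
        recordings.append(simulate_recording(config, label, rng,
                                             subject_id=f"S{idx:03d}"))
    return recordings


def stop_bang_label(criteria, threshold: int = 5) -> int:
    """Binary risk label from the 8 STOP-BANG questionnaire criteria.

    Returns 1 iff strictly more than `threshold` criteria are met. The
    strict ``>`` reading is the default; screening practice often uses
    ``>= 5``, which corresponds to ``threshold=4`` here.
    """
    criteria = list(criteria)
    if len(criteria) != 8:
        raise ValueError(f"STOP-BANG has exactly 8 criteria, got {len(criteria)}")
    if not 0 <= threshold <= 8:
        raise ValueError("threshold must lie in [0, 8]")
    return int(sum(bool(c) for c in criteria) > threshold)


def tiny_cohort_config(**overrides) -> CohortConfig:
    """Small, fast cohort used by examples and smoke tests."""
    base = CohortConfig(n_subjects=8, channels=4, duration=120.0, seed=7)
    return replace(base, **overrides)
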