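"""File formats: cohort containers, EDF ingest, checkpoints, manifests, configs.

The lossless interchange format for cohorts and features is a single-file
compressed numpy container (``.npz``) with the documented layout below; EDF
recordings are read through mne when present. EDF writing requires an EDF
backend (edfio) and raises a clear error when none is importable — EDF is
16-bit quantized, so the container is also the more faithful format.

Cohort container layout (npz):
    signals        (n_subjects, channels, samples) float64
    labels         (n_subjects,) int
    contexts       (n_subjects, context_dim) float64
    onsets         (n_subjects, n_onsets) float64 (stimulus onsets, seconds)
    sampling_rate  scalar
    subject_ids    (n_subjects,) unicode

Feature container layout (npz): features (n, T, d), labels, contexts,
subject_ids, frame_rate, manifest_json.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alht import ModelConfig
from .cohort import CohortConfig, LabeledRecording
from .network import AblationFlags
from .preprocessing import PreprocessConfig, WindowDataset
from .training import TrainConfig

__all__ = [
    "MalformedHeaderError", "SamplingRateMismatchError", "MissingLabelError",
    "save_cohort", "load_cohort", "read_recording", "write_edf",
    "save_dataset", "load_dataset", "save_checkpoint", "load_checkpoint",
    "RunManifest", "write_manifest", "load_yaml_config", "file_digest",
]


class MalformedHeaderError(ValueError):
    """Recording file exists but its header cannot be parsed."""
    code = "malformed_header"


class SamplingRateMismatchError(ValueError):
    """Channels of one recording disagree on sampling rate."""
    code = "sampling_rate_mismatch"


class MissingLabelError(KeyError):
    """No label row found for a recording in the sidecar table."""
    code = "missing_label"


# --------------------------------------------------------------------------
# cohort container
# --------------------------------------------------------------------------

def save_cohort(recordings: list[LabeledRecording], path, labels_csv=None) -> None:
    """Write the cohort to the npz container (plus optional labels CSV)."""
    path = Path(path)
    signals = np.stack([r.signal for r in recordings])
    onset_len = max((len(r.stimulus_onsets) for r in recordings), default=0)
    onsets = np.full((len(recordings), onset_len), np.nan)
    for i, r in enumerate(recordings):
        onsets[i, :len(r.stimulus_onsets)] = r.stimulus_onsets
    np.savez_compressed(
        path,
        signals=signals,
        labels=np.array([r.label for r in recordings]),
        contexts=np.stack([r.context for r in recordings]),
        onsets=onsets,
        sampling_rate=np.array(recordings[0].sampling_rate),
        subject_ids=np.array([r.subject_id for r in recordings]))
    if labels_csv is not None:
        rows = []
        for r in recordings:
            row = {"subject_id": r.subject_id, "label": r.label}
            row.update({f"context_{i}": v for i, v in enumerate(r.context)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(labels_csv, index=False)


def load_cohort(path) -> list[LabeledRecording]:
    with np.load(path, allow_pickle=False) as data:
        required = {"signals", "labels", "contexts", "onsets", "sampling_rate",
                    "subject_ids"}
        missing = required - set(data.files)
        if missing:
            raise MalformedHeaderError(f"container missing arrays: {sorted(missing)}")
        fs = float(data["sampling_rate"])
        recs = []
        for i in range(data["signals"].shape[0]):
            onsets = data["onsets"][i]
            recs.append(LabeledRecording(
                signal=data["signals"][i], sampling_rate=fs,
                label=int(data["labels"][i]), context=data["contexts"][i],
                subject_id=str(data["subject_ids"][i]),
                stimulus_onsets=onsets[~np.isnan(onsets)]))
    return recs


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def read_recording(path, labels_csv=None, subject_id: str | None = None
                   ) -> LabeledRecording:
    """Read one recording from EDF or from the npz container.

    For EDF, the label and context are joined from the sidecar CSV
    (columns: subject_id, label, context_*); a missing row raises
    MissingLabelError rather than defaulting silently.
    """
    path = Path(path)
    if path.suffix.lower() == ".npz":
        cohort = load_cohort(path)
        if subject_id is None:
            return cohort[0]
        for rec in cohort:
            if rec.subject_id == subject_id:
                return rec
        raise MissingLabelError(f"subject {subject_id!r} not in container")
    if path.suffix.lower() == ".edf":
        import mne
        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:
            raise MalformedHeaderError(f"cannot parse EDF header of {path}: {exc}")
        sfreqs = {float(raw.info["sfreq"])}
        if len(sfreqs) != 1:
            raise SamplingRateMismatchError(f"mixed sampling rates in {path}")
        sid = subject_id or path.stem
        if labels_csv is None:
            raise MissingLabelError("EDF recordings need a sidecar labels CSV")
        table = pd.read_csv(labels_csv)
        row = table[table["subject_id"] == sid]
        if row.empty:
            raise MissingLabelError(f"no label row for subject {sid!r} in {labels_csv}")
        row = row.iloc[0]
        context_cols = sorted(c for c in table.columns if c.startswith("context_"))
        context = row[context_cols].to_numpy(dtype=float) if context_cols else np.zeros(1)
        return LabeledRecording(signal=raw.get_data(), sampling_rate=float(raw.info["sfreq"]),
                                label=int(row["label"]), context=context, subject_id=sid)
    raise MalformedHeaderError(f"unsupported recording format: {path.suffix!r}")


def write_edf(recording: LabeledRecording, path) -> None:
    """Export one recording as EDF (16-bit quantized) if a backend exists."""
    try:
        import mne
        import edfio  # noqa: F401  (mne's EDF export backend)
    except ImportError as exc:
        raise RuntimeError(
            "EDF export needs the 'edfio' backend; use the npz container "
            f"(save_cohort) for lossless storage. ({exc})") from exc
    info = mne.create_info([f"EEG{i:03d}" for i in range(recording.signal.shape[0])],
                           sfreq=recording.sampling_rate, ch_types="eeg")
    raw = mne.io.RawArray(recording.signal * 1e-6, info, verbose="error")
    mne.export.export_raw(str(path), raw, fmt="edf", overwrite=True, verbose="error")


# --------------------------------------------------------------------------
# feature datasets
# --------------------------------------------------------------------------

def save_dataset(dataset: WindowDataset, path) -> None:
    np.savez_compressed(path, features=dataset.features, labels=dataset.labels,
                        contexts=dataset.contexts,
                        subject_ids=np.array(dataset.subject_ids),
                        frame_rate=np.array(dataset.frame_rate),
                        manifest_json=np.array(json.dumps(dataset.manifest)))


def load_dataset(path) -> WindowDataset:
    with np.load(path, allow_pickle=False) as data:
        return WindowDataset(features=data["features"], labels=data["labels"],
                             contexts=data["contexts"],
                             subject_ids=[str(s) for s in data["subject_ids"]],
                             frame_rate=float(data["frame_rate"]),
                             manifest=json.loads(str(data["manifest_json"])))


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(checkpoint: dict, path) -> None:
    """Single-file checkpoint: parameter arrays + embedded JSON config."""
    meta = {
        "model_config": dataclasses.asdict(checkpoint["model_config"]),
        "train_config": dataclasses.asdict(checkpoint["train_config"]),
        "ablation": dataclasses.asdict(checkpoint["ablation"]),
        "seed": checkpoint["seed"],
        "best_epoch": checkpoint["best_epoch"],
        "best_val_loss": checkpoint["best_val_loss"],
        "d_in": checkpoint["d_in"],
        "context_dim": checkpoint["context_dim"],
    }
    arrays = {f"param::{k}": v for k, v in checkpoint["state_dict"].items()}
    np.savez_compressed(path, meta_json=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    mc = dict(meta["model_config"])
    mc["vocab"] = tuple(mc["vocab"])
    return {"state_dict": state,
            "model_config": ModelConfig(**mc),
            "train_config": TrainConfig(**meta["train_config"]),
            "ablation": AblationFlags(**meta["ablation"]),
            "seed": meta["seed"], "best_epoch": meta["best_epoch"],
            "best_val_loss": meta["best_val_loss"],
            "d_in": meta["d_in"], "context_dim": meta["context_dim"]}


# --------------------------------------------------------------------------
# manifests and configs
# --------------------------------------------------------------------------

def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record tying every output file to its configuration."""

    command: str
    config: dict
    seeds: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    tool_version: str = "0.1.0"
    timestamp: str = ""

    def finalize(self) -> "RunManifest":
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)


_CONFIG_SECTIONS = {
    "cohort": CohortConfig,
    "preprocess": PreprocessConfig,
    "model": ModelConfig,
    "train": TrainConfig,
}


def load_yaml_config(path) -> dict:
    """Load and validate a YAML config with cohort/preprocess/model/train sections.

    Unknown sections or keys are rejected before any computation starts.
    Tuple-valued fields accept YAML lists.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out: dict = {}
    for section, cls in _CONFIG_SECTIONS.items():
        payload = dict(raw.get(section) or {})
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - valid
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        for key, value in payload.items():
            if isinstance(value, list):
                payload[key] = tuple(value)
        cfg = cls(**payload)
        if hasattr(cfg, "validate"):
            cfg.validate()
        out[section] = cfg
    return out
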