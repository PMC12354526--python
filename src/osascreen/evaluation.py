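"""Binary screening metrics and multi-run aggregation.

Point metrics come from the confusion matrix (accuracy, sensitivity = recall
= TP/(TP+FN), specificity = TN/(TN+FP), F1); AUC-ROC is the rank-based
Mann-Whitney estimator with midrank tie handling. Replicate runs are
aggregated as mean +/- sample standard deviation (ddof = 1).

Zero-denominator conventions: sensitivity or specificity with an empty class
is reported as None with a flag; F1 with zero precision + recall is 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["MetricsReport", "confusion_metrics", "auc_roc", "aggregate_runs",
           "evaluate_windows", "subject_report", "roc_points"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "auc")


@dataclass
class MetricsReport:
    """Screening metrics with optional multi-run mean/std."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    f1: float
    auc: float | None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_runs: int = 1
    per_run: dict = field(default_factory=dict)   # metric -> list of run values
    std: dict = field(default_factory=dict)       # metric -> sample std
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1, "auc": self.auc,
                "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
                "n_runs": self.n_runs, "per_run": self.per_run, "std": self.std,
                "flags": list(self.flags)}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_binary(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{what} is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} must be binary (0/1)")
    return arr.astype(int)


def confusion_metrics(labels, predictions) -> MetricsReport:
    """Point metrics from binary labels and hard predictions."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    flags: list[str] = []
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    if sensitivity is None:
        flags.append("sensitivity undefined (no positives in labels)")
    if specificity is None:
        flags.append("specificity undefined (no negatives in labels)")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = sensitivity if sensitivity is not None else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, f1=f1, auc=None,
                         tp=tp, fp=fp, tn=tn, fn=fn, flags=flags)


def auc_roc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y = _check_binary(labels, "labels")
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC requires both classes in labels")
    return float(roc_auc_score(y, s))


def roc_points(labels, scores) -> np.ndarray:
    """(threshold-free) ROC curve points as an array of (fpr, tpr)."""
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(_check_binary(labels, "labels"), np.asarray(scores))
    return np.column_stack([fpr, tpr])


def evaluate_windows(labels, predictions, scores=None) -> MetricsReport:
    """Window-level report; adds AUC when continuous scores are supplied."""
    report = confusion_metrics(labels, predictions)
    if scores is not None:
        try:
            report.auc = auc_roc(labels, scores)
        except ValueError:
            report.flags.append("auc undefined (single-class labels)")
    return report


def aggregate_runs(reports: list[MetricsReport]) -> MetricsReport:
    """Mean and sample std (ddof=1) per metric across seeded runs.

    A single run is reported with std 0 and a flag; confusion counts are
    summed across runs.
    """
    if not reports:
        raise ValueError("need at least one report")
    per_run: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    flags: list[str] = []
    for r in reports:
        for m in METRIC_NAMES:
            value = getattr(r, m)
            if value is not None:
                per_run[m].append(float(value))
        flags.extend(r.flags)
    means: dict[str, float | None] = {}
    stds: dict[str, float] = {}
    for m, vals in per_run.items():
        if not vals:
            means[m], stds[m] = None, 0.0
            continue
        # sort before reducing so the aggregate is invariant to run order,
        # and short-circuit identical runs to an exact zero spread
        ordered = sorted(vals)
        means[m] = float(np.mean(ordered))
        if len(ordered) < 2 or ordered[0] == ordered[-1]:
            stds[m] = 0.0
        else:
            stds[m] = float(np.std(ordered, ddof=1))
    if len(reports) == 1:
        flags.append("single run: std reported as 0")
    return MetricsReport(accuracy=means["accuracy"], sensitivity=means["sensitivity"],
                         specificity=means["specificity"], f1=means["f1"],
                         auc=means["auc"],
                         tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
                         tn=sum(r.tn for r in reports), fn=sum(r.fn for r in reports),
                         n_runs=len(reports), per_run=per_run, std=stds,
                         flags=sorted(set(flags)))


def subject_report(subject_ids, labels, predictions, scores=None) -> MetricsReport:
    """Secondary subject-level report: majority vote over a subject's windows.

    Scores are averaged per subject for the AUC. Ties in the vote go to the
    high-risk class (screening errs toward sensitivity).
    """
    ids = np.asarray(subject_ids)
    y = _check_binary(labels, "labels")
    p = _check_binary(predictions, "predictions")
    subj = sorted(set(ids.tolist()))
    s_labels, s_preds, s_scores = [], [], []
    for s in subj:
        m = ids == s
        s_labels.append(int(round(y[m].mean())))
        s_preds.append(1 if p[m].mean() >= 0.5 else 0)
        if scores is not None:
            s_scores.append(float(np.mean(np.asarray(scores)[m])))
    return evaluate_windows(np.array(s_labels), np.array(s_preds),
                            np.array(s_scores) if scores is not None else None)
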