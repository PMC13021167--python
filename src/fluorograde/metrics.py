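"""Evaluation statistics: Dice/Jaccard overlap, Cohen's kappa (plain and
quadratic-weighted), ROC AUC, and per-task report assembly.

Dice and Jaccard are linked by the identity D = 2J / (1 + J); both are
reported because segmentation literature quotes either.  Kappa follows the
weighted definition kappa = 1 - (sum w*O) / (sum w*E) with w_ij = (i-j)^2
for quadratic weights and the disagreement indicator for unweighted; AUC is
the Mann-Whitney probability that a random positive outscores a random
negative, ties counted one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError

BINARY_THRESHOLD = 0.5  # decision threshold for all binary tasks


class TaskSpec(str, Enum):
    """The four learning tasks the pipeline trains and evaluates."""

    LOW_VS_HEALTHY = "low_vs_healthy"
    HIGH_VS_HEALTHY = "high_vs_healthy"
    HIGH_VS_LOW = "high_vs_low"
    CANCER_SEG = "cancer_seg"


@dataclass
class MetricsReport:
    task: TaskSpec
    n: int
    accuracy: Optional[float] = None
    kappa: Optional[float] = None
    kappa_quadratic: Optional[float] = None
    auc: Optional[float] = None
    dice_per_class: Optional[dict[str, float]] = None
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "task": self.task.value,
            "n": self.n,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "kappa_quadratic": self.kappa_quadratic,
            "auc": self.auc,
        }
        if self.dice_per_class:
            for k, v in self.dice_per_class.items():
                row[f"dice_{k}"] = v
        row.update(self.extra)
        return row


def dice_jaccard(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Overlap of two binary rasters.  Two empty masks agree perfectly by
    convention -> (1.0, 1.0), avoiding NaN on absent classes."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    sa, sb = np.count_nonzero(a), np.count_nonzero(b)
    if sa + sb == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (sa + sb)
    jaccard = inter / (sa + sb - inter)
    return dice, jaccard


def cohen_kappa(y_true, y_pred, weights: str = "none") -> float:
    """Chance-corrected agreement between two label sequences.

    ``weights='quadratic'`` penalises ordinal disagreements by (i-j)^2.
    When truth and prediction are each a single constant class the statistic
    is undefined 0/0; it is defined here as 1 for identical constants and 0
    otherwise, with a warning.
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("label sequences must be equal-length and non-empty")
    if weights not in ("none", "quadratic"):
        raise ValueError(f"unknown weights {weights!r}")

    labels = np.unique(np.concatenate([y_true, y_pred]))
    k = labels.size
    if k == 1:
        warnings.warn("single-class truth and prediction; kappa defined by guard")
        return 1.0
    lut = {v: i for i, v in enumerate(labels)}
    ti = np.array([lut[v] for v in y_true])
    pi = np.array([lut[v] for v in y_pred])
    observed = np.zeros((k, k))
    np.add.at(observed, (ti, pi), 1.0)
    n = y_true.size
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    idx = np.arange(k)
    if weights == "quadratic":
        w = (idx[:, None] - idx[None, :]) ** 2
    else:
        w = (idx[:, None] != idx[None, :]).astype(float)
    denom = float((w * expected).sum())
    if denom == 0.0:
        warnings.warn("degenerate chance agreement; kappa defined by guard")
        return 1.0 if float((w * observed).sum()) == 0.0 else 0.0
    return 1.0 - float((w * observed).sum()) / denom


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = float(ranks[labels == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate(task: TaskSpec, predictions, truth) -> MetricsReport:
    """Assemble the metric subset appropriate to a task.

    Binary tasks take probability scores and 0/1 labels; segmentation takes
    3-class label rasters (lists or arrays of equal shape), predictions
    either as label rasters or as probability stacks with class as the
    trailing axis.
    """
    if task is TaskSpec.CANCER_SEG:
        pred_list = [np.asarray(p) for p in predictions]
        true_list = [np.asarray(t) for t in truth]
        pred_labels = [
            p.argmax(axis=-1) if p.ndim == t.ndim + 1 else p
            for p, t in zip(pred_list, true_list)
        ]
        pred_flat = np.concatenate([p.ravel() for p in pred_labels])
        true_flat = np.concatenate([t.ravel() for t in true_list])
        class_names = {0: "background", 1: "healthy", 2: "cancer"}
        dice = {}
        for cls, name in class_names.items():
            d, _ = dice_jaccard(pred_flat == cls, true_flat == cls)
            dice[name] = d
        return MetricsReport(
            task=task,
            n=len(true_list),
            accuracy=float((pred_flat == true_flat).mean()),
            kappa=cohen_kappa(true_flat, pred_flat, "none"),
            kappa_quadratic=cohen_kappa(true_flat, pred_flat, "quadratic"),
            dice_per_class=dice,
        )

    scores = np.asarray(predictions, dtype=float).ravel()
    labels = np.asarray(truth).ravel().astype(int)
    decisions = (scores >= BINARY_THRESHOLD).astype(int)
    report = MetricsReport(
        task=task,
        n=labels.size,
        accuracy=float((decisions == labels).mean()),
        kappa=cohen_kappa(labels, decisions, "none"),
        kappa_quadratic=cohen_kappa(labels, decisions, "quadratic"),
    )
    try:
        report.auc = roc_auc(scores, labels)
    except UndefinedMetricError:
        report.auc = None
    return report
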