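"""Multi-label evaluation metrics.

Eight metrics summarise a score matrix against binary labels:

* ``ap``, ``auroc``, ``aupr`` — macro averages of per-label average
  precision, ROC AUC and precision–recall AUC (labels that are constant in
  the evaluation set are skipped with a warning);
* ``acc`` — example-based Jaccard accuracy at threshold 0.5;
* ``fmax`` — protein-centric F1 maximised over thresholds 0.01 … 0.99
  (CAFA convention: precision is averaged over proteins with at least one
  predicted label, recall over proteins with at least one true label);
* ``hloss`` — Hamming loss at threshold 0.5;
* ``rl`` — ranking loss: the mean fraction of (positive, negative) label
  pairs ordered incorrectly within an example (ties count half);
* ``oerror`` — one-error: the fraction of examples whose top-scored label
  is not a true positive.

Lower is better for the last three; everything lives in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, auc,
                             precision_recall_curve, roc_auc_score)

__all__ = ["MetricReport", "evaluate", "fmax_score", "pr_curves"]

FMAX_THRESHOLDS = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class MetricReport:
    ap: float
    auroc: float
    aupr: float
    acc: float
    fmax: float
    hloss: float
    rl: float
    oerror: float
    fmax_threshold: float = 0.5
    per_class: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("ap", "auroc", "aupr", "acc", "fmax", "hloss", "rl", "oerror")}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _macro(metric_fn, scores, labels, name):
    vals = []
    skipped = 0
    for j in range(labels.shape[1]):
        col = labels[:, j]
        if col.min() == col.max():
            skipped += 1
            continue
        vals.append(metric_fn(col, scores[:, j]))
    if skipped:
        warnings.warn(f"{name}: skipped {skipped} single-class labels",
                      stacklevel=3)
    if not vals:
        warnings.warn(f"{name}: no label with both classes; returning nan",
                      stacklevel=3)
        return float("nan")
    return float(np.mean(vals))


def _aupr_single(y, s):
    precision, recall, _ = precision_recall_curve(y, s)
    return auc(recall, precision)


def fmax_score(scores: np.ndarray, labels: np.ndarray):
    """Protein-centric Fmax and the threshold attaining it."""
    best_f, best_t = 0.0, FMAX_THRESHOLDS[0]
    pos_counts = labels.sum(axis=1)
    for t in FMAX_THRESHOLDS:
        pred = scores >= t
        n_pred = pred.sum(axis=1)
        tp = (pred & (labels > 0)).sum(axis=1)
        covered = n_pred > 0
        if not covered.any():
            continue
        precision = (tp[covered] / n_pred[covered]).mean()
        with_pos = pos_counts > 0
        recall = (tp[with_pos] / pos_counts[with_pos]).mean() if with_pos.any() else 0.0
        if precision + recall == 0:
            continue
        f1 = 2 * precision * recall / (precision + recall)
        if f1 > best_f:
            best_f, best_t = f1, t
    return float(best_f), float(best_t)


def _ranking_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    vals = []
    for i in range(scores.shape[0]):
        pos = scores[i, labels[i] > 0]
        neg = scores[i, labels[i] == 0]
        if pos.size == 0 or neg.size == 0:
            continue
        wrong = (pos[:, None] < neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        vals.append((wrong + 0.5 * ties) / (pos.size * neg.size))
    return float(np.mean(vals)) if vals else float("nan")


def _one_error(scores: np.ndarray, labels: np.ndarray) -> float:
    has_pos = labels.sum(axis=1) > 0
    if not has_pos.any():
        return float("nan")
    top = scores[has_pos].argmax(axis=1)
    return float(np.mean(labels[has_pos, top] == 0))


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> MetricReport:
    """Compute the full metric suite for an N×C score/label pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} vs labels {labels.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        warnings.warn("labels are all-constant; ranking metrics undefined",
                      stacklevel=2)

    ap = _macro(average_precision_score, scores, labels, "AP")
    auroc = _macro(roc_auc_score, scores, labels, "AUROC")
    aupr = _macro(_aupr_single, scores, labels, "AUPR")

    pred = scores >= threshold
    inter = (pred & (labels > 0)).sum(axis=1)
    union = (pred | (labels > 0)).sum(axis=1)
    jaccard = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    acc = float(jaccard.mean())

    fmax, fmax_t = fmax_score(scores, labels)
    hloss = float((pred != (labels > 0)).mean())
    rl = _ranking_loss(scores, labels)
    oerror = _one_error(scores, labels)
    return MetricReport(ap=ap, auroc=auroc, aupr=aupr, acc=acc, fmax=fmax,
                        hloss=hloss, rl=rl, oerror=oerror, fmax_threshold=fmax_t,
                        per_class=None)


def pr_curves(scores: np.ndarray, labels: np.ndarray,
              class_names: list[str] | None = None) -> pd.DataFrame:
    """Per-class precision–recall curves as a long-format table."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_classes = labels.shape[1]
    names = class_names or [f"class_{j}" for j in range(n_classes)]
    frames = []
    for j in range(n_classes):
        if labels[:, j].sum() == 0:
            warnings.warn(f"{names[j]}: no positives; empty PR curve",
                          stacklevel=2)
            continue
        precision, recall, _ = precision_recall_curve(labels[:, j], scores[:, j])
        frames.append(pd.DataFrame({"class": names[j], "recall": recall,
                                    "precision": precision}))
    if not frames:
        return pd.DataFrame(columns=["class", "recall", "precision"])
    return pd.concat(frames, ignore_index=True)
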