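"""Validation metrics for presence/absence classification.

All metrics are threshold-independent rank statistics (AUC_ROC, AUC_PR)
or confusion-matrix rates (sensitivity, specificity), computed natively so
their conventions — midrank tie handling for AUC_ROC, step-wise average
precision for AUC_PR — are explicit and testable against brute force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricSet", "auc_roc", "auc_pr", "sens_spec", "summarize_iterations"]


@dataclass
class MetricSet:
    """Validation metrics for one model iteration."""

    auc_roc: float
    auc_pr: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int)


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 1/2. Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_roc needs both classes present")
    ranks = rankdata(scores)  # midranks for ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_pr(scores, labels) -> float:
    """Area under the precision-recall curve as average precision.

    AP = Σ_i (R_i − R_{i−1}) · P_i over the operating points obtained by
    thresholding at each unique score in descending order — the standard
    step-wise estimator, with no trapezoidal interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("auc_pr needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # operating points: last index of each unique score value
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def sens_spec(predicted_binary, labels) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP))."""
    pred = _check_binary(predicted_binary)
    labels = _check_binary(labels)
    pos = labels == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("sens_spec needs both classes present")
    sensitivity = float((pred[pos] == 1).mean())
    specificity = float((pred[neg] == 0).mean())
    return sensitivity, specificity


def summarize_iterations(metric_sets) -> dict[str, dict[str, float]]:
    """Mean and population SD of each metric across iterations."""
    metric_sets = list(metric_sets)
    if not metric_sets:
        raise ValueError("no metric sets to summarize")
    out: dict[str, dict[str, float]] = {}
    for name in ("auc_roc", "auc_pr", "sensitivity", "specificity"):
        vals = np.array([getattr(m, name) for m in metric_sets], dtype=float)
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    return out
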