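"""Classification metrics, ROC/AUC, and entropy-based uncertainty triage.

AUC is the rank statistic: the probability that a uniformly random positive
outscores a uniformly random negative, ties counting one half — identical
to the trapezoidal area under the ROC curve over all distinct thresholds.

Prediction uncertainty is the base-2 entropy of the output probability,
H(p) = -p log2 p - (1-p) log2(1-p), in [0, 1] bits. Screening calls are
stratified by flagging the top fraction (default 10%) of samples by
entropy, and by fixed bins at H < 0.3, 0.3 <= H < 0.6, H >= 0.6. Base-2 is
the only base under which the empirically useful flagging thresholds near
1 bit are attainable (the natural-log maximum is ln 2 ~ 0.693).
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


@dataclass
class UncertaintyReport:
    entropy: np.ndarray  # per sample, bits
    flagged: np.ndarray  # bool, top `top_fraction` by entropy
    threshold: float  # realized entropy threshold
    top_fraction: float
    bin_edges: tuple = (0.3, 0.6)
    bin_metrics: list = field(default_factory=list)  # one dict per bin


def _confusion(probs, labels, threshold):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return tp, fp, tn, fn


def classification_metrics(
    probs, labels, threshold: float = 0.5
) -> MetricsReport:
    """Confusion-matrix metrics at a decision threshold (default 0.5).

    Precision/recall/F1 are 0 (with a warning) when their denominator is 0.
    AUC is included when both classes are present, else NaN.
    """
    tp, fp, tn, fn = _confusion(probs, labels, threshold)
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n

    def safe_div(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (0/0); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = safe_div(tp, tp + fp, "precision")
    recall = safe_div(tp, tp + fn, "recall")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    labels_arr = np.asarray(labels, dtype=int)
    auc = (
        roc_auc(probs, labels_arr)
        if 0 < labels_arr.sum() < labels_arr.size
        else float("nan")
    )
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        threshold=threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def roc_auc(probs, labels) -> float:
    """Rank-based AUC (Mann-Whitney); ties count one half."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(probs)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(probs, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, FPR, TPR) over all distinct scores plus both endpoints.

    Thresholds are decreasing; the first row (threshold above every score)
    is (0, 0) and the last (threshold at/below every score) is (1, 1).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    distinct = np.unique(probs)[::-1]
    thresholds = np.concatenate(([distinct[0] + 1.0], distinct))
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = probs >= t
        tpr[i] = (pred & (labels == 1)).sum() / n_pos
        fpr[i] = (pred & (labels == 0)).sum() / n_neg
    return thresholds, fpr, tpr


def trapezoid_auc(probs, labels) -> float:
    """Trapezoidal area under the ROC curve (equals the rank AUC)."""
    _, fpr, tpr = roc_curve_points(probs, labels)
    return float(np.trapezoid(tpr, fpr))


def export_roc(probs, labels, path: str | os.PathLike) -> None:
    """CSV of (threshold, fpr, tpr) covering all distinct score thresholds."""
    thresholds, fpr, tpr = roc_curve_points(probs, labels)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "fpr", "tpr"])
        for t, x, y in zip(thresholds, fpr, tpr):
            writer.writerow([repr(float(t)), repr(float(x)), repr(float(y))])


def binary_entropy(p) -> np.ndarray | float:
    """H(p) in bits; 0 log 0 = 0; errors outside [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(arr > 0, arr * np.log2(arr), 0.0) - np.where(
            arr < 1, (1 - arr) * np.log2(1 - arr), 0.0
        )
    h = np.clip(h, 0.0, 1.0)
    return float(h) if np.isscalar(p) or arr.ndim == 0 else h


def uncertainty_stratify(
    probs,
    labels=None,
    top_fraction: float = 0.10,
    bin_edges: tuple = (0.3, 0.6),
) -> UncertaintyReport:
    """Entropy-based triage of screening calls.

    Flags the ``top_fraction`` most-uncertain samples (stable tie handling:
    sort by entropy descending, then index ascending) and, when labels are
    given, reports accuracy/F1 within the entropy bins.
    """
    probs = np.asarray(probs, dtype=float)
    n = probs.size
    if n < 1:
        raise ValueError("need at least one sample")
    h = binary_entropy(probs)
    k = int(np.floor(n * top_fraction + 0.5))
    order = np.lexsort((np.arange(n), -h))  # entropy desc, index asc
    flagged = np.zeros(n, dtype=bool)
    flagged[order[:k]] = True
    threshold = float(h[order[k - 1]]) if k > 0 else float(h.max()) + np.inf
    if k == 0:
        threshold = float("inf")

    bin_metrics = []
    edges = (-np.inf,) + tuple(bin_edges) + (np.inf,)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (h >= lo) & (h < hi)
        entry = {
            "lo": float(lo),
            "hi": float(hi),
            "n": int(mask.sum()),
            "accuracy": float("nan"),
            "f1": float("nan"),
        }
        if labels is not None and mask.any():
            sub_labels = np.asarray(labels, dtype=int)[mask]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = classification_metrics(probs[mask], sub_labels)
            entry["accuracy"] = m.accuracy
            entry["f1"] = m.f1
        bin_metrics.append(entry)
    return UncertaintyReport(
        entropy=h,
        flagged=flagged,
        threshold=threshold,
        top_fraction=top_fraction,
        bin_edges=tuple(bin_edges),
        bin_metrics=bin_metrics,
    )
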