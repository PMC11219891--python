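"""Classification metrics: confusion counting, precision/recall/F1,
accuracy and error rate, RMSE, Cohen's kappa, and distribution shape
(skewness/kurtosis).

Undefined quantities (zero denominators) are reported as NaN, never as 0.
Kurtosis follows the Pearson convention (normal distribution -> 3); the
excess value (normal -> 0) is available via ``excess=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "confusion_per_class",
    "precision",
    "recall",
    "specificity",
    "f1",
    "accuracy",
    "error_rate",
    "rmse",
    "kappa",
    "skewness",
    "kurtosis",
    "report",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies for one positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Count TP/FP/FN/TN with the given class treated as positive."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        t_pos = t == positive_class
        p_pos = p == positive_class
        if t_pos and p_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif p_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def confusion_per_class(y_true, y_pred) -> dict:
    """One-vs-rest confusion counts for every class present in y_true."""
    return {c: confusion(y_true, y_pred, c) for c in sorted(set(y_true))}


def precision(c: ConfusionCounts, paper_literal: bool = False) -> float:
    """TP / (TP + FP).

    ``paper_literal=True`` reproduces, for audit, a variant sometimes seen
    in print that divides by (TP + FN) — which is recall's denominator —
    instead of the standard (TP + FP).
    """
    denom = c.TP + (c.FN if paper_literal else c.FP)
    return c.TP / denom if denom > 0 else UNDEFINED


def recall(c: ConfusionCounts) -> float:
    """Sensitivity TP / (TP + FN)."""
    denom = c.TP + c.FN
    return c.TP / denom if denom > 0 else UNDEFINED


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP)."""
    denom = c.TN + c.FP
    return c.TN / denom if denom > 0 else UNDEFINED


def f1(c: ConfusionCounts) -> float:
    """2 TP / (2 TP + FN + FP) — the harmonic mean of precision and recall."""
    denom = 2 * c.TP + c.FN + c.FP
    return 2 * c.TP / denom if denom > 0 else UNDEFINED


def accuracy(c: ConfusionCounts) -> float:
    return (c.TP + c.TN) / c.n if c.n > 0 else UNDEFINED


def error_rate(c: ConfusionCounts) -> float:
    """Misclassification fraction, 1 - accuracy."""
    return 1.0 - accuracy(c) if c.n > 0 else UNDEFINED


def rmse(targets, predictions) -> float:
    """Root mean squared error sqrt(mean((b_s - f(a_s))^2))."""
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.shape != p.shape:
        raise ValueError("targets and predictions must have equal length")
    if t.size == 0:
        raise ValueError("rmse of an empty sample is undefined")
    return float(np.sqrt(np.mean((t - p) ** 2)))


def kappa(y_true, y_pred) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e), in [-1, 1].

    When both raters use a single shared class (p_e = 1), kappa is defined
    as 1 for perfect agreement and NaN otherwise.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    n = len(y_true)
    if n == 0:
        return UNDEFINED
    classes = sorted(set(y_true) | set(y_pred))
    p_o = sum(t == p for t, p in zip(y_true, y_pred)) / n
    p_e = sum(
        (y_true.count(c) / n) * (y_pred.count(c) / n) for c in classes
    )
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else UNDEFINED
    return (p_o - p_e) / (1.0 - p_e)


def skewness(sample) -> float:
    """Third standardized moment (population convention)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = np.std(x)
    if sd == 0:
        return UNDEFINED
    z = (x - np.mean(x)) / sd
    return float(np.mean(z ** 3))


def kurtosis(sample, excess: bool = False) -> float:
    """Fourth standardized moment; Pearson convention by default
    (normal -> 3), or excess (normal -> 0) with ``excess=True``."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = np.std(x)
    if sd == 0:
        return UNDEFINED
    z = (x - np.mean(x)) / sd
    k = float(np.mean(z ** 4))
    return k - 3.0 if excess else k


def report(y_true, y_pred, positive_class) -> dict:
    """Full metric report for one positive class, JSON-serialisable."""
    c = confusion(y_true, y_pred, positive_class)
    scores = np.asarray([1.0 if p == positive_class else -1.0 for p in y_pred])
    rep = {
        "counts": {"TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN},
        "accuracy": accuracy(c),
        "error_rate": error_rate(c),
        "precision": precision(c),
        "recall": recall(c),
        "specificity": specificity(c),
        "f1": f1(c),
        "kappa": kappa(list(y_true), list(y_pred)),
    }
    if len(scores) >= 3 and np.std(scores) > 0:
        rep["score_skewness"] = skewness(scores)
        rep["score_kurtosis"] = kurtosis(scores)
    # replace NaN with None for clean JSON
    return {k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in rep.items()}
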