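"""Confusion-based metrics, Mann-Whitney ROC AUC, DeLong variance with
normal-approximation confidence intervals, and the dice overlap utility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AUCEstimate:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __post_init__(self):
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("confidence interval does not contain the AUC")


def _as_arrays(probabilities, labels):
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.size} probabilities vs {y.size} labels")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return p, y


def confusion_at_threshold(probabilities, labels, threshold: float) -> ConfusionCounts:
    """Counts with the decision rule: predict 1 iff p >= threshold."""
    p, y = _as_arrays(probabilities, labels)
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def summary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy = (TP+TN)/total."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive labels")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative labels")
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty cohort")
    return {
        "sensitivity": c.tp / (c.tp + c.fn),
        "specificity": c.tn / (c.tn + c.fp),
        "accuracy": (c.tp + c.tn) / c.total,
    }


def _placements(p, y):
    """DeLong placement values via midranks: V10 (one per case) and V01
    (one per control)."""
    cases = p[y == 1]
    controls = p[y == 0]
    n1, n0 = cases.size, controls.size
    ranks_all = sstats.rankdata(np.concatenate([cases, controls]))
    ranks_cases = sstats.rankdata(cases)
    ranks_controls = sstats.rankdata(controls)
    v10 = (ranks_all[:n1] - ranks_cases) / n0
    v01 = 1.0 - (ranks_all[n1:] - ranks_controls) / n1
    return v10, v01


def roc_auc(probabilities, labels) -> float:
    """Mann-Whitney AUC: concordant pairs count 1, ties count 1/2."""
    p, y = _as_arrays(probabilities, labels)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("roc_auc requires both classes")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    # numerator is a sum of exact halves, so this matches brute-force pair
    # counting bit-for-bit
    ranks_all = sstats.rankdata(p)
    ranks_cases = sstats.rankdata(p[y == 1])
    numerator = float(np.sum(ranks_all[y == 1] - ranks_cases))
    return numerator / (n1 * n0)


def delong_ci(probabilities, labels, alpha: float = 0.05) -> AUCEstimate:
    """AUC with DeLong variance and a normal-approximation CI clipped to [0, 1]."""
    p, y = _as_arrays(probabilities, labels)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 < 2 or n0 < 2:
        raise ValueError(f"delong_ci requires >= 2 of each class, got n1={n1}, n0={n0}")
    v10, v01 = _placements(p, y)
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1))
    s01 = float(np.var(v01, ddof=1))
    variance = s10 / n1 + s01 / n0
    z = sstats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(variance)
    return AUCEstimate(
        auc=auc,
        variance=variance,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        alpha=alpha,
    )


def dice_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); two empty masks score 1 by convention."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(a & b)) / denom
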