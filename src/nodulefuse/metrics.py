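"""Confusion-matrix metrics, ROC/AUC and DeLong confidence intervals.

Malignant is the positive class everywhere.  AUC is computed with the rank
(Mann-Whitney) statistic with midrank tie handling, which equals the
trapezoidal area under the empirical ROC curve; its confidence interval
uses DeLong's placement-value variance.  Report values are rounded
half-away-from-zero to two decimals, and AUC is reported in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Confusion-derived metrics; ``None`` marks an undefined denominator."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    balanced_accuracy: float | None
    auc_pct: float | None = None
    auc_ci: tuple[float, float] | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None:
                out[k] = None
            elif k == "auc_ci":
                out[k] = (round_half_away(v[0], ndigits), round_half_away(v[1], ndigits))
            else:
                out[k] = round_half_away(v, ndigits)
        return out


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves going away from zero (0.005 -> 0.01), as in clinical tables."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def confusion(predicted: Sequence[int], true: Sequence[int]) -> ConfusionMatrix:
    """Count the 2x2 table of binary predictions vs truth (malignant = 1)."""
    pred = np.asarray(predicted, dtype=int)
    y = np.asarray(true, dtype=int)
    if pred.size != y.size:
        raise ValueError("predicted and true labels differ in length")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sens/spec/PPV/NPV/F1/BAcc from a confusion matrix (ROC fields empty)."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        balanced_accuracy=(sens + spec) / 2 if sens is not None and spec is not None else None,
    )


def roc_auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the normalized Mann-Whitney statistic with midrank ties."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    r = rankdata(p)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(probs: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC points (FPR, TPR), from (0, 0) to (1, 1)."""
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("ROC needs both classes")
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(probs, float), drop_intermediate=False)
    return fpr, tpr


def delong_ci(
    probs: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, clipped to [0, 1].

    Uses the placement-value variance: with ``V10_i`` the placement of
    positive score i among the negatives and ``V01_j`` the converse,
    ``var(AUC) = var(V10)/n1 + var(V01)/n0``.  A degenerate variance
    (e.g. perfect separation) collapses the interval onto the AUC.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = p[y == 1], p[y == 0]
    n1, n0 = pos.size, neg.size
    if n1 < 5 or n0 < 5:
        raise ValueError("DeLong CI needs at least 5 observations per class")
    # placement values via midranks
    v10 = np.empty(n1)
    v01 = np.empty(n0)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n0
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / n1
    auc = v10.mean()
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    if var <= 0:
        return (auc, auc)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def full_report(probs: Sequence[float], labels: Sequence[int], threshold: float) -> MetricReport:
    """Metrics at a threshold plus AUC (percent) and its DeLong 95% CI."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    rep = classification_metrics(confusion((p >= threshold).astype(int), y))
    rep.auc_pct = 100.0 * roc_auc(p, y)
    lo, hi = delong_ci(p, y)
    rep.auc_ci = (100.0 * lo, 100.0 * hi)
    return rep
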