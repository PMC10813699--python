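"""Shared model-selection utilities: elbow cutoff, threshold search, patient pooling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .tables import MALIGNANT

if TYPE_CHECKING:  # pragma: no cover
    from .tables import OmicsTable

COLLINEAR_TOL = 1e-12


@dataclass
class FeatureRanking:
    """Descending per-feature scores with an elbow cutoff.

    ``selected`` holds the top ``elbow_k`` features, the working feature set
    for a final model.
    """

    features: list[str]
    scores: np.ndarray
    elbow_k: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be sorted descending")
        if not 1 <= self.elbow_k <= len(self.features):
            raise ValueError("elbow_k out of range")

    @property
    def selected(self) -> list[str]:
        return self.features[: self.elbow_k]


def elbow_cutoff(scores: Sequence[float]) -> int:
    """Knee of a descending score curve via maximum deviation from its chord.

    The chord joins ``(1, score_1)`` and ``(m, score_m)`` and the deviation
    of each point from it is examined (the perpendicular distance differs
    from the vertical deviation only by the constant chord-angle cosine, so
    the argmax is identical).  Two regimes:

    * plateau-then-drop curves bulge *above* the chord; the knee is the
      point of maximum positive deviation — the last score of the plateau,
      which is kept (``k = argmax``);
    * steep-drop-then-tail (convex) curves sag *below* the chord; the point
      of maximum sag is the first score of the tail, so everything before
      it is kept (``k = argmax - 1``).

    The regime with the larger absolute deviation wins; ties go to the
    smallest k.  A curve collinear with its chord (within ``1e-12``, e.g.
    exactly linear decay) has no knee and everything is kept, except in the
    degenerate two-point case where the tie rule on the (all-zero)
    deviations keeps the first point.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    if np.ptp(s) == 0:
        raise ValueError("elbow undefined for all-equal scores")
    if np.any(np.diff(s) > 0):
        raise ValueError("scores must be sorted descending")
    m = s.size
    if m == 2:
        return 1
    x = np.arange(1, m + 1, dtype=float)
    chord = s[0] + (s[-1] - s[0]) * (x - 1) / (m - 1)
    d = s - chord
    if np.abs(d).max() < COLLINEAR_TOL:
        return m
    i_above = int(np.argmax(d))
    i_below = int(np.argmax(-d))
    if d[i_above] >= -d[i_below]:
        return i_above + 1
    return max(i_below, 1)


def optimize_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Probability cutoff maximizing balanced accuracy of ``prob >= t``.

    Candidates are the midpoints of consecutive distinct sorted
    probabilities plus 0.5; ties are broken toward the smallest candidate
    (favoring sensitivity).  ``labels`` are binary with malignant = 1.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size != y.size or p.size == 0:
        raise ValueError("probs and labels must be equal-length and non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold optimization needs both classes")
    uniq = np.unique(p)
    cands = np.unique(np.concatenate([(uniq[:-1] + uniq[1:]) / 2.0, [0.5]]))
    if uniq.size == 1:
        warnings.warn("degenerate probabilities: all equal, BAcc is 0.5", stacklevel=2)
    pred = p[None, :] >= cands[:, None]          # (n_cand, n)
    sens = (pred & (y == 1)).sum(axis=1) / n_pos
    spec = (~pred & (y == 0)).sum(axis=1) / n_neg
    bacc = (sens + spec) / 2.0
    best = bacc.max()
    return float(cands[np.nonzero(bacc >= best - 1e-15)[0][0]])


def balanced_accuracy(probs: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """BAcc of the rule ``prob >= threshold -> malignant``."""
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(probs, dtype=float) >= threshold
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("balanced accuracy needs both classes")
    sens = (pred & (y == 1)).sum() / n_pos
    spec = (~pred & (y == 0)).sum() / n_neg
    return float((sens + spec) / 2.0)


def aggregate_patient(nodule_probs: Sequence[float]) -> float:
    """Patient-level malignancy probability: the worst (maximum) nodule."""
    p = np.asarray(nodule_probs, dtype=float)
    if p.size == 0:
        raise ValueError("patient has no nodule probabilities")
    return float(p.max())


def patient_level(table: "OmicsTable", probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pool row-level probabilities to patients (worst nodule, sorted by id).

    Returns ``(patient_probs, patient_labels)`` with malignant = 1; the
    patient label follows the any-malignant-nodule rule.  Classification is
    ultimately of patients, so thresholds and balanced accuracies are
    computed on this scale everywhere.
    """
    s = pd.Series(np.asarray(probs, float), index=table.patient_ids.to_numpy())
    pooled = s.groupby(level=0).max()
    y = (table.patient_labels()[pooled.index] == MALIGNANT).to_numpy(int)
    return pooled.to_numpy(), y
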