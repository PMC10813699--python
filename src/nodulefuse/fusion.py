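"""Late fusion of two modalities' prediction sets.

Each modality contributes a :class:`PredictionSet`: per-patient malignancy
probabilities plus the model's decision threshold.  Four combination rules
are supported — Stouffer's method on the probit scale, mean, maximum and
product — and each rule is applied *identically* to the probabilities and
to the thresholds, so the fused decision is ``combined prob >= combined
threshold``.

Stouffer's method combines standard-normal scores; classifier probabilities
are mapped there by the probit transform (with symmetric clipping at
``1e-6``) and the combined score is returned through the normal CDF:
``Phi((probit(p1) + probit(p2)) / sqrt(2))``, the unweighted two-source
form.  Note the product rule is deliberately *not* scale-invariant: jointly
rescaling probabilities and thresholds changes decisions.  That is a
property of the scheme being modeled, not a defect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)

CLIP_EPS = 1e-6


def _clip(p: np.ndarray | float) -> np.ndarray | float:
    clipped = np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS)
    if np.any(clipped != np.asarray(p)):
        log.debug("probabilities clipped to [%g, %g] for the probit transform",
                  CLIP_EPS, 1 - CLIP_EPS)
    return clipped


def stouffer_combine(p1, p2):
    """Unweighted two-source Stouffer combination on the probit scale."""
    z = (norm.ppf(_clip(p1)) + norm.ppf(_clip(p2))) / np.sqrt(2.0)
    return norm.cdf(z)


def mean_combine(p1, p2):
    return (np.asarray(p1, float) + np.asarray(p2, float)) / 2.0


def max_combine(p1, p2):
    return np.maximum(p1, p2)


def product_combine(p1, p2):
    return np.asarray(p1, float) * np.asarray(p2, float)


COMBINERS: dict[str, Callable] = {
    "stouffer": stouffer_combine,
    "mean": mean_combine,
    "max": max_combine,
    "product": product_combine,
}


@dataclass
class PredictionSet:
    """Per-patient malignancy probabilities with a decision threshold."""

    probabilities: pd.Series      # index: patient_id
    threshold: float
    modality: str
    model: str                    # "LR" or "RF"

    def __post_init__(self) -> None:
        p = self.probabilities.astype(float)
        if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must be finite and in [0, 1]")
        self.threshold = float(np.clip(self.threshold, CLIP_EPS, 1 - CLIP_EPS))
        self.probabilities = p

    def predicted_labels(self) -> pd.Series:
        return (self.probabilities >= self.threshold).astype(int)


@dataclass
class IntegratedPrediction:
    """Fused probabilities/threshold on the patient intersection of two sets."""

    probabilities: pd.Series
    threshold: float
    method: str
    sources: tuple[str, str]

    def predicted_labels(self) -> pd.Series:
        return (self.probabilities >= self.threshold).astype(int)


def integrate_predictions(
    a: PredictionSet, b: PredictionSet, method: str
) -> IntegratedPrediction:
    """Fuse two prediction sets with the chosen rule.

    The rule combines per-patient probabilities over the intersection of
    the two sets' patients, and the two thresholds with the same rule.
    """
    if method not in COMBINERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(COMBINERS)}")
    if a.model != b.model:
        warnings.warn(
            f"integrating across model families ({a.model} vs {b.model})", stacklevel=2
        )
    common = a.probabilities.index.intersection(b.probabilities.index)
    if len(common) == 0:
        raise ValueError("no patients common to both prediction sets")
    fn = COMBINERS[method]
    probs = pd.Series(
        np.asarray(fn(a.probabilities[common].to_numpy(), b.probabilities[common].to_numpy()),
                   dtype=float),
        index=common,
    )
    thr = float(fn(np.asarray([a.threshold]), np.asarray([b.threshold]))[0])
    return IntegratedPrediction(
        probs, thr, method, (f"{a.model}:{a.modality}", f"{b.model}:{b.modality}")
    )
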