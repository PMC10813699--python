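"""Robust benign-referenced standardization and pre-model feature filtering.

Feature scales differ wildly across radiomic texture families and metabolite
classes, and both are heavily skewed, so standardization uses non-parametric
location/scale statistics (median, IQR) computed on the *benign* samples
within each acquisition cohort.  Referencing the benign class makes the
transform double as a batch correction: benign samples end up with median 0
and IQR 1 per feature in every cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .tables import BENIGN, META_COLUMNS, OmicsTable

log = logging.getLogger(__name__)

MIN_BENIGN_PER_COHORT = 8


@dataclass
class StandardizationReference:
    """Fitted per-cohort benign medians/IQRs plus features dropped as degenerate."""

    medians: dict[str, pd.Series]   # cohort -> per-feature benign median
    iqrs: dict[str, pd.Series]      # cohort -> per-feature benign IQR (Q3 - Q1)
    dropped: list[str]
    features: list[str]

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "dropped": self.dropped,
            "medians": {c: s.to_dict() for c, s in self.medians.items()},
            "iqrs": {c: s.to_dict() for c, s in self.iqrs.items()},
        }


def fit_standardizer(table: OmicsTable) -> StandardizationReference:
    """Learn benign median/IQR per feature within each cohort.

    IQR is Q3 - Q1 with linear-interpolation (type-7) quantiles.  Features
    whose benign IQR is zero in any cohort are flagged and excluded (they are
    constant or near-constant and carry no usable scale).
    """
    medians: dict[str, pd.Series] = {}
    iqrs: dict[str, pd.Series] = {}
    degenerate: set[str] = set()
    feats = table.feature_names
    for cohort, sub in table.data.groupby("cohort"):
        ben = sub.loc[sub["label"] == BENIGN, feats]
        if len(ben) < MIN_BENIGN_PER_COHORT:
            raise ValueError(
                f"cohort {cohort!r} has only {len(ben)} benign observations "
                f"(need >= {MIN_BENIGN_PER_COHORT})"
            )
        q1, med, q3 = np.percentile(ben.to_numpy(float), [25, 50, 75], axis=0)
        iqr = q3 - q1
        medians[cohort] = pd.Series(med, index=feats)
        iqrs[cohort] = pd.Series(iqr, index=feats)
        degenerate.update(np.asarray(feats)[iqr == 0])
    if degenerate:
        log.warning("dropping %d features with zero benign IQR: %s",
                    len(degenerate), sorted(degenerate)[:10])
    kept = [f for f in feats if f not in degenerate]
    if not kept:
        raise ValueError("all features degenerate (zero benign IQR)")
    return StandardizationReference(
        medians={c: s[kept] for c, s in medians.items()},
        iqrs={c: s[kept] for c, s in iqrs.items()},
        dropped=sorted(degenerate),
        features=kept,
    )


def apply_standardizer(table: OmicsTable, ref: StandardizationReference) -> OmicsTable:
    """Apply a fitted reference: x' = (x - median_benign,cohort) / IQR_benign,cohort."""
    out = table.data[list(META_COLUMNS) + ref.features].copy()
    out[ref.features] = out[ref.features].astype(float)
    for cohort, sub in out.groupby("cohort"):
        if cohort not in ref.medians:
            raise KeyError(f"cohort {cohort!r} absent from the fitted reference")
        vals = sub[ref.features].to_numpy(float)
        vals = (vals - ref.medians[cohort].to_numpy()) / ref.iqrs[cohort].to_numpy()
        out.loc[sub.index, ref.features] = vals
    return OmicsTable(out, table.modality)


def robust_standardize(table: OmicsTable) -> tuple[OmicsTable, StandardizationReference]:
    """Fit on the table's own benign samples and transform in one step."""
    ref = fit_standardizer(table)
    return apply_standardizer(table, ref), ref


def drop_missing_features(
    table: OmicsTable, max_missing_fraction: float = 0.2
) -> tuple[OmicsTable, dict]:
    """Remove features missing above the threshold, then rows with remaining NaNs.

    Returns the cleaned table and a report with the dropped feature names and
    removed sample ids.
    """
    feats = table.feature_names
    frac = table.data[feats].isna().mean()
    dropped = sorted(frac.index[frac > max_missing_fraction])
    kept = [f for f in feats if f not in dropped]
    if not kept:
        raise ValueError("all features exceed the missingness threshold")
    sub = table.data[list(META_COLUMNS) + kept]
    row_ok = sub[kept].notna().all(axis=1)
    removed_rows = sorted(sub.loc[~row_ok, "sample_id"])
    out = OmicsTable(sub.loc[row_ok].copy(), table.modality)
    report = {"dropped_features": dropped, "removed_samples": removed_rows}
    return out, report


def correlation_filter(
    table: OmicsTable,
    threshold: float = 0.95,
    priority: Mapping[str, float] | None = None,
) -> tuple[OmicsTable, list[str]]:
    """Greedy removal of highly rank-correlated features.

    While any feature pair has Spearman ``|rho|`` above ``threshold``, the
    pair with the largest ``|rho|`` is visited and its lower-priority member
    (smaller ``|r_g|`` score; ties broken toward the lexicographically later
    name) is removed.  ``priority`` maps feature name to its univariate
    effect size; missing entries count as 0.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    feats = table.feature_names
    prio = {f: abs(float((priority or {}).get(f, 0.0))) for f in feats}
    if len(feats) < 2:
        return table, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        rho = stats.spearmanr(table.data[feats].to_numpy(float)).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.abs(rho)
    np.fill_diagonal(rho, 0.0)
    rho = np.nan_to_num(rho, nan=0.0)

    alive = np.ones(len(feats), dtype=bool)
    removed: list[str] = []
    while True:
        sub = np.where(alive)[0]
        block = rho[np.ix_(sub, sub)]
        if block.size == 0 or block.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(block), block.shape)
        a, b = feats[sub[i]], feats[sub[j]]
        # remove the weaker member; on equal priority drop the later name
        if prio[a] < prio[b]:
            loser = a
        elif prio[b] < prio[a]:
            loser = b
        else:
            loser = max(a, b)
        alive[feats.index(loser)] = False
        removed.append(loser)
    survivors = [f for f in feats if f not in set(removed)]
    return table.select_features(survivors), removed
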