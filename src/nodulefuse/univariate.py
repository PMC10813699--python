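"""Per-feature non-parametric screening: normality, rank tests, effect sizes, FDR.

Features in both modalities are strongly skewed, so group differences are
assessed with the Mann-Whitney test and summarized by the rank-biserial
correlation ``r_g = 1 - 2U/(n1*n2)``, the standard effect-size companion of
the U statistic.  ``U`` counts wins of *group1* over *group2* (scipy's
convention), so ``r_g > 0`` means group2 is stochastically larger; in
reports group1 is benign and group2 malignant, making positive ``r_g`` an
"up in malignant" effect.  Multiplicity is controlled with
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import BENIGN, MALIGNANT, OmicsTable

SHAPIRO_MAX_N = 5000


def shapiro_screen(values: np.ndarray, max_n: int = SHAPIRO_MAX_N) -> float:
    """Shapiro-Wilk p-value; subsamples (seeded) above ``max_n`` observations."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    if x.size > max_n:
        x = np.random.default_rng(0).choice(x, size=max_n, replace=False)
    return float(stats.shapiro(x).pvalue)


def mann_whitney(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U (wins of group1) with a two-sided p-value.

    The p-value is exact when ``min(n1, n2) <= 8`` and the pooled sample has
    no ties, and uses the tie-corrected normal approximation with continuity
    correction otherwise.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(g1.size, g2.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation ``1 - 2U/(n1*n2)`` for U = wins of group1."""
    if not 0 <= U <= n1 * n2:
        raise ValueError("U must lie in [0, n1*n2]")
    return 1.0 - 2.0 * U / (n1 * n2)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_report(table: OmicsTable) -> pd.DataFrame:
    """Screen every feature benign-vs-malignant.

    Returns a DataFrame (one row per feature, sorted by ``|r_g|``
    descending) with columns ``feature, shapiro_p, U, p, r_g, q, direction``.
    ``direction`` is "up" when the malignant median exceeds the benign one.
    """
    labels = table.labels
    if labels.nunique() < 2:
        raise ValueError("univariate screening needs both classes")
    ben = labels == BENIGN
    mal = labels == MALIGNANT
    X = table.X
    n1, n2 = int(ben.sum()), int(mal.sum())
    rows = []
    for j, name in enumerate(table.feature_names):
        x = X[:, j]
        b, m = x[ben.to_numpy()], x[mal.to_numpy()]
        try:
            sw = shapiro_screen(x)
        except ValueError:
            sw = np.nan
        U, p = mann_whitney(b, m)
        rg = rank_biserial(U, n1, n2)
        direction = "up" if np.median(m) >= np.median(b) else "down"
        rows.append((name, sw, U, p, rg, direction))
    out = pd.DataFrame(rows, columns=["feature", "shapiro_p", "U", "p", "r_g", "direction"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out[["feature", "shapiro_p", "U", "p", "r_g", "q", "direction"]]
    return out.reindex(out["r_g"].abs().sort_values(ascending=False).index).reset_index(drop=True)
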