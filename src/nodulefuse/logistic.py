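"""Logistic-regression arm of the pipeline.

Per multiple-random-cross-validation (MRCV) repeat: a stratified
patient-grouped 70/30 split, forward feature selection under a
``delta BIC <= 2`` stop rule on the training subset, balanced-accuracy
evaluation on both subsets, and a BAcc-maximizing probability threshold
estimated on the validation subset.  Features are then ranked across the
repeats by proportional order of addition weighted by validation BAcc, an
elbow cutoff picks the working set, and the final model is refit on the
full training table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np
from scipy.special import expit

from . import selection
from .splits import stratified_patient_split
from .tables import OmicsTable

SCORE_TOL = 1e-8
MAX_ITER = 100
RIDGE_FALLBACK = 1e-6
COEF_CAP = 30.0  # |beta| beyond this on standardized inputs signals separation

__all__ = [
    "LRModel", "LRFoldResult", "fit_logistic", "forward_bic_select",
    "mrcv_lr", "rank_features_lr", "finalize_lr",
]


@dataclass
class LRModel:
    """Fitted logistic model: feature names, coefficients, decision threshold."""

    features: list[str]
    intercept: float
    coef: np.ndarray
    threshold: float | None = None
    loglik: float = np.nan
    converged: bool = True
    ridged: bool = False

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.size != len(self.features):
            raise ValueError("one coefficient per feature required")
        if not np.all(np.isfinite(self.coef)) or not np.isfinite(self.intercept):
            raise ValueError("coefficients must be finite")

    def predict_proba(self, X: np.ndarray | OmicsTable) -> np.ndarray:
        if isinstance(X, OmicsTable):
            X = X.data[self.features].to_numpy(float)
        eta = self.intercept + np.asarray(X, float) @ self.coef
        return expit(eta)

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "threshold": self.threshold,
        }


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable sum of y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X1: np.ndarray, y: np.ndarray, ridge: float, beta0: np.ndarray | None):
    n, k = X1.shape
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    converged = False
    for _ in range(MAX_ITER):
        eta = X1 @ beta
        p = expit(eta)
        score = X1.T @ (y - p) - ridge * beta
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-10, None)
        H = (X1 * w[:, None]).T @ X1 + ridge * np.eye(k)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return beta, -np.inf, False
        # step-halving keeps the likelihood monotone on nasty designs
        ll0 = _loglik(eta, y) - 0.5 * ridge * beta @ beta
        for _ in range(30):
            cand = beta + step
            ll1 = _loglik(X1 @ cand, y) - 0.5 * ridge * cand @ cand
            if ll1 >= ll0 - 1e-12:
                break
            step *= 0.5
        beta = beta + step
    return beta, _loglik(X1 @ beta, y), converged


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    warm_start: np.ndarray | None = None,
) -> LRModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence: ``max |score| < 1e-8`` or 100 iterations.  Diverging
    coefficients (perfect separation) trigger a warning and a refit with a
    tiny ridge penalty (1e-6) that caps the estimates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y) and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, ll, converged = _irls(X1, y, ridge=0.0, beta0=warm_start)
    ridged = False
    if not converged or not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > COEF_CAP:
        warnings.warn(
            "possible perfect separation: refitting with ridge 1e-6", stacklevel=2
        )
        beta, ll, converged = _irls(X1, y, ridge=RIDGE_FALLBACK, beta0=None)
        ridged = True
    return LRModel(
        features=names, intercept=float(beta[0]), coef=beta[1:],
        loglik=ll, converged=converged, ridged=ridged,
    )


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion ``k ln n - 2 lnL`` (k counts the intercept)."""
    return k * np.log(n) - 2.0 * loglik


def forward_bic_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    delta_stop: float = 2.0,
) -> tuple[list[str], list[float]]:
    """Forward stepwise selection with a BIC-improvement stop rule.

    Starting from the intercept-only model, each step fits every
    single-feature addition and adds the one with the lowest BIC, provided
    the improvement over the current model exceeds ``delta_stop`` BIC units;
    otherwise selection stops.  Ties break lexicographically on the feature
    name.  The returned ``bic_path`` starts at the intercept-only BIC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(feature_names)
    if X.shape[1] != len(names):
        raise ValueError("feature_names must match X columns")
    n = len(y)
    chosen: list[int] = []
    ones = np.ones((n, 1))
    beta_cur, ll0, _ = _irls(ones, y, ridge=0.0, beta0=None)
    current_bic = bic(ll0, 1, n)
    path = [current_bic]
    remaining = list(range(X.shape[1]))
    # lexicographic candidate order makes the np.argmin tie-break lexicographic
    remaining.sort(key=lambda j: names[j])
    while remaining:
        k = len(chosen)
        design = np.empty((n, k + 2))
        design[:, 0] = 1.0
        if k:
            design[:, 1:k + 1] = X[:, chosen]
        warm = np.append(beta_cur, 0.0)
        bics = np.empty(len(remaining))
        betas: list[np.ndarray] = []
        for idx, j in enumerate(remaining):
            design[:, -1] = X[:, j]
            beta, ll, _ = _irls(design, y, ridge=0.0, beta0=warm)
            bics[idx] = bic(ll, k + 2, n)
            betas.append(beta)
        best = int(np.argmin(bics))
        if current_bic - bics[best] <= delta_stop:
            break
        j = remaining.pop(best)
        chosen.append(j)
        beta_cur = betas[best]
        current_bic = float(bics[best])
        path.append(current_bic)
    return [names[j] for j in chosen], path


@dataclass
class LRFoldResult:
    fold_index: int
    ordered_features: list[str]
    bic_path: list[float]
    bacc_train: float
    bacc_valid: float
    threshold: float


def _fold_eval(
    train: OmicsTable, valid: OmicsTable, features: list[str]
) -> tuple[float, float, float, LRModel]:
    # threshold and BAcc are computed on patient-pooled probabilities: the
    # decision is per patient, and the final threshold is applied to
    # patient-level scores
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_logistic(
            train.data[features].to_numpy(float) if features else np.empty((train.n_samples, 0)),
            train.y, feature_names=features,
        )
    p_tr, y_tr = selection.patient_level(train, model.predict_proba(train))
    p_va, y_va = selection.patient_level(valid, model.predict_proba(valid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr = selection.optimize_threshold(p_va, y_va)
    thr = float(np.clip(thr, 1e-6, 1 - 1e-6))
    return (
        selection.balanced_accuracy(p_tr, y_tr, thr),
        selection.balanced_accuracy(p_va, y_va, thr),
        thr,
        model,
    )


def mrcv_lr(
    train: OmicsTable,
    n_repeats: int = 100,
    train_frac: float = 0.70,
    delta_stop: float = 2.0,
    seed: int = 0,
) -> list[LRFoldResult]:
    """Multiple random cross-validation of the logistic arm (default 100 x 70/30)."""
    if train.labels.nunique() < 2:
        raise ValueError("training table needs both classes")
    rng = np.random.default_rng(seed)
    folds: list[LRFoldResult] = []
    feats = train.feature_names
    for r in range(n_repeats):
        tr, va = stratified_patient_split(train, train_frac, rng)
        ordered, path = forward_bic_select(
            tr.data[feats].to_numpy(float), tr.y, feats, delta_stop=delta_stop
        )
        bacc_tr, bacc_va, thr, _ = _fold_eval(tr, va, ordered)
        folds.append(LRFoldResult(r, ordered, path, bacc_tr, bacc_va, thr))
    return folds


def rank_features_lr(folds: Sequence[LRFoldResult]) -> selection.FeatureRanking:
    """Aggregate forward-selection orders across folds into one ranking.

    In a fold that selected ``m`` features, the feature added at position
    ``j`` (1-based) receives weight ``(m - j + 1)/m``; its score is the sum
    over folds of that weight times the fold's validation BAcc.
    """
    if not folds:
        raise ValueError("no folds")
    scores: dict[str, float] = {}
    any_selected = False
    for f in folds:
        m = len(f.ordered_features)
        if m == 0:
            continue
        any_selected = True
        for j, name in enumerate(f.ordered_features, start=1):
            scores[name] = scores.get(name, 0.0) + (m - j + 1) / m * f.bacc_valid
    if not any_selected:
        raise ValueError("every fold selected zero features; nothing to rank")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [k for k, _ in items]
    vals = np.array([v for _, v in items])
    k = 1 if len(names) == 1 else selection.elbow_cutoff(vals)
    return selection.FeatureRanking(names, vals, k)


def finalize_lr(
    train: OmicsTable,
    ranking: selection.FeatureRanking,
    folds: Sequence[LRFoldResult],
) -> LRModel:
    """Refit on the full training table with the elbow-selected features.

    The decision threshold is the median of the per-fold validation
    thresholds (the repeats estimate it; the median aggregates robustly).
    """
    feats = ranking.selected
    if not feats:
        raise ValueError("elbow selected no features")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_logistic(train.data[feats].to_numpy(float), train.y, feature_names=feats)
    model.threshold = float(np.clip(median(f.threshold for f in folds), 1e-6, 1 - 1e-6))
    return model
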