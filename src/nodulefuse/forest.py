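"""Random-forest arm of the pipeline.

A forest of fully grown CART trees fit on *weighted* bootstrap samples:
each tree's bootstrap draws rows with probability proportional to
``w_i = N / (2 N_class(i))``, so both classes contribute equally in
expectation regardless of the benign/malignant imbalance.  Out-of-bag (OOB)
membership is recorded per tree for the permutation variable importance: a
feature's importance is the per-tree drop in OOB accuracy after permuting
that feature within the OOB rows, averaged over trees and normalized by its
standard error, ``mean(delta) / (sd(delta)/sqrt(ntree))``.

The MRCV loop tunes ``mtry`` (features sampled per split, 5..30) and
``ntree`` (100/500/1000/2000) by validation balanced accuracy over repeated
stratified patient-grouped 80/20 splits.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from statistics import median
from typing import Callable, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from . import selection
from .splits import stratified_patient_split
from .tables import OmicsTable

__all__ = [
    "RFConfig", "RFFoldResult", "RandomForest", "fit_forest",
    "permutation_importance", "mrcv_rf", "rank_features_rf", "finalize_rf",
    "class_balance_weights", "fast_rf_config",
]


@dataclass(frozen=True)
class RFConfig:
    """MRCV settings for the forest arm (canonical defaults)."""

    mtry_grid: tuple[int, ...] = tuple(range(5, 31))
    ntree_grid: tuple[int, ...] = (100, 500, 1000, 2000)
    n_repeats: int = 100
    train_frac: float = 0.80
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if not self.mtry_grid or not self.ntree_grid:
            raise ValueError("parameter grids must be non-empty")


def fast_rf_config(n_repeats: int = 25) -> RFConfig:
    """Reduced, non-canonical grid for quick runs (labeled as such in provenance).

    A single (mtry=15, ntree=500) point: mtry near the square-root-of-p
    default of classical random forests, and a tree count large enough that
    the standard-error-normalized permutation importance keeps a usable
    signal-to-noise ratio (its z-scores scale with sqrt(ntree); basing
    fast-mode importance on 100-tree forests, the noisiest corner of the
    canonical grid, misrepresents the canonical procedure).
    """
    return RFConfig(mtry_grid=(15,), ntree_grid=(500,), n_repeats=n_repeats)


def class_balance_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights ``N / (2 N_class)``: each class gets half the mass."""
    y = np.asarray(y, dtype=int)
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("class weighting needs both classes")
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


@dataclass
class RandomForest:
    """A fitted weighted-bootstrap forest with retained OOB bookkeeping."""

    trees: list[DecisionTreeClassifier]
    oob_masks: np.ndarray          # (ntree, n_train) bool, True = out of bag
    feature_names: list[str]
    mtry: int
    sample_weights: np.ndarray | None = None
    threshold: float | None = None

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def _votes(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for t in self.trees:
            votes += t.predict(X)
        return votes

    def predict_proba(self, X: np.ndarray | OmicsTable) -> np.ndarray:
        """Fraction of trees voting malignant."""
        if isinstance(X, OmicsTable):
            X = X.data[self.feature_names].to_numpy(float)
        return self._votes(X) / self.ntree

    def to_dict(self) -> dict:
        """Portable structured form: per-tree node arrays, no pickled objects."""
        out = []
        for t in self.trees:
            tr = t.tree_
            leaf_vote = [int(t.classes_[np.argmax(v)]) for v in tr.value.squeeze(axis=1)]
            out.append({
                "feature": tr.feature.tolist(),
                "threshold": tr.threshold.tolist(),
                "children_left": tr.children_left.tolist(),
                "children_right": tr.children_right.tolist(),
                "leaf_vote": leaf_vote,
            })
        return {"features": self.feature_names, "mtry": self.mtry, "trees": out}


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    ntree: int,
    sample_weights: np.ndarray | None = None,
    rng: np.random.Generator | int = 0,
    feature_names: Sequence[str] | None = None,
) -> RandomForest:
    """Fit ``ntree`` Gini CART trees on weighted bootstrap samples.

    ``sample_weights`` scale the bootstrap draw probabilities (uniform when
    None).  Trees are fully grown (no depth limit, minimum leaf size 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if np.unique(y).size < 2:
        raise ValueError("forest fitting needs both classes")
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must lie in [1, {p}]")
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    prob = None
    if sample_weights is not None:
        w = np.asarray(sample_weights, dtype=float)
        prob = w / w.sum()
    trees: list[DecisionTreeClassifier] = []
    oob = np.zeros((ntree, n), dtype=bool)
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    for b in range(ntree):
        idx = rng.choice(n, size=n, replace=True, p=prob)
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        oob[b] = mask
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=mtry,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return RandomForest(trees, oob, names, mtry,
                        sample_weights=None if prob is None else w)


def permutation_importance(
    forest: RandomForest,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | int = 0,
    permute: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    return_deltas: bool = False,
):
    """OOB permutation importance, normalized by the standard error.

    For each tree and feature: ``delta = OOB accuracy - OOB accuracy after
    permuting the feature within the tree's OOB rows``.  The importance is
    ``mean(delta) / (sd(delta)/sqrt(ntree))`` with the convention that a
    zero standard deviation (e.g. a feature no tree ever used) yields 0.

    When the forest was fit with class-balancing weights, the OOB accuracy
    is the *weighted* fraction correct under those same weights.  Trees
    trained on balanced bootstraps over-call the minority class on the raw
    (imbalanced) OOB rows, so the plain accuracy can *increase* when a
    genuinely informative feature is destroyed; weighting the accuracy the
    same way as the training objective keeps the importance sign meaningful.

    ``permute`` is a test hook mapping ``(rng, n) -> permutation`` (defaults
    to a uniform random permutation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    perm_fn = permute or (lambda g, n: g.permutation(n))
    p = X.shape[1]
    weights = forest.sample_weights
    deltas = np.zeros((forest.ntree, p))
    for b, tree in enumerate(forest.trees):
        oob_idx = np.nonzero(forest.oob_masks[b])[0]
        if oob_idx.size == 0:
            continue
        Xo, yo = X[oob_idx], y[oob_idx]
        wo = np.ones(oob_idx.size) if weights is None else weights[oob_idx]
        wo = wo / wo.sum()
        base_acc = (tree.predict(Xo) == yo) @ wo
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size == 0:
            continue
        # one batched predict per tree over all used-feature permutations
        n_o = oob_idx.size
        stacked = np.tile(Xo, (used.size, 1))
        for k, j in enumerate(used):
            perm = perm_fn(rng, n_o)
            stacked[k * n_o:(k + 1) * n_o, j] = Xo[perm, j]
        preds = tree.predict(stacked).reshape(used.size, n_o)
        accs = (preds == yo) @ wo
        deltas[b, used] = base_acc - accs
    deltas[np.abs(deltas) < 1e-12] = 0.0   # summation-order dust
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = deltas.std(axis=0, ddof=1) if forest.ntree > 1 else np.zeros(p)
        imp = np.where(sd > 0, deltas.mean(axis=0) / (sd / np.sqrt(forest.ntree)), 0.0)
    if return_deltas:
        return imp, deltas
    return imp


@dataclass
class RFFoldResult:
    fold_index: int
    best_mtry: int
    best_ntree: int
    importance: np.ndarray         # aligned with the candidate feature list
    bacc_train: float
    bacc_valid: float
    threshold: float


def mrcv_rf(
    train: OmicsTable,
    config: RFConfig | None = None,
    seed: int = 0,
) -> tuple[list[RFFoldResult], tuple[int, int]]:
    """MRCV of the forest arm: per-repeat grid tuning, importance, threshold.

    Per repeat the (mtry, ntree) grid is evaluated on a fresh stratified
    patient-grouped split; the pair maximizing validation BAcc (ties toward
    smaller ntree, then smaller mtry) supplies the fold's importance vector
    and threshold.  Returns the fold results and the modal best pair.
    """
    config = config or RFConfig()
    if train.labels.nunique() < 2:
        raise ValueError("training table needs both classes")
    rng = np.random.default_rng(seed)
    feats = train.feature_names
    p = len(feats)
    grid = sorted(
        {(min(m, p), t) for m in config.mtry_grid for t in config.ntree_grid},
        key=lambda mt: (mt[1], mt[0]),
    )
    folds: list[RFFoldResult] = []
    for r in range(config.n_repeats):
        tr, va = stratified_patient_split(train, config.train_frac, rng)
        Xtr, ytr = tr.X, tr.y
        Xva = va.X
        weights = class_balance_weights(ytr) if config.class_weighting else None
        best = None
        # tuning, thresholding and BAcc all on patient-pooled probabilities
        for mtry, ntree in grid:
            f = fit_forest(Xtr, ytr, mtry, ntree, weights, rng, feats)
            p_va, y_va = selection.patient_level(va, f.predict_proba(Xva))
            bacc = selection.balanced_accuracy(p_va, y_va, 0.5)
            if best is None or bacc > best[0] + 1e-12:
                best = (bacc, mtry, ntree, f)
        _, mtry, ntree, forest = best
        p_va, y_va = selection.patient_level(va, forest.predict_proba(Xva))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = float(np.clip(selection.optimize_threshold(p_va, y_va), 1e-6, 1 - 1e-6))
        imp = permutation_importance(forest, Xtr, ytr, rng)
        p_tr, y_tr = selection.patient_level(tr, forest.predict_proba(Xtr))
        folds.append(RFFoldResult(
            r, mtry, ntree, imp,
            selection.balanced_accuracy(p_tr, y_tr, thr),
            selection.balanced_accuracy(p_va, y_va, thr),
            thr,
        ))
    pairs = Counter((f.best_mtry, f.best_ntree) for f in folds)
    top = max(pairs.values())
    tuned = min((mt for mt, c in pairs.items() if c == top), key=lambda mt: (mt[1], mt[0]))
    return folds, tuned


def rank_features_rf(
    folds: Sequence[RFFoldResult], feature_names: Sequence[str]
) -> selection.FeatureRanking:
    """Mean importance across repeats, descending, with an elbow cutoff.

    Only features with positive mean importance enter the elbow; if none
    has, there is no signal to cut and an error is raised.
    """
    if not folds:
        raise ValueError("no folds")
    mean_imp = np.mean([f.importance for f in folds], axis=0)
    order = sorted(range(len(feature_names)),
                   key=lambda j: (-mean_imp[j], feature_names[j]))
    names = [feature_names[j] for j in order]
    vals = mean_imp[order]
    pos = int(np.sum(vals > 0))
    if pos == 0:
        raise ValueError("all mean importances are non-positive; no elbow exists")
    if pos == 1:
        k = 1
    else:
        k = selection.elbow_cutoff(vals[:pos])
    return selection.FeatureRanking(names, vals, k)


def finalize_rf(
    train: OmicsTable,
    ranking: selection.FeatureRanking,
    tuned: tuple[int, int],
    folds: Sequence[RFFoldResult],
    seed: int = 0,
    class_weighting: bool = True,
) -> RandomForest:
    """Refit on the full training table restricted to the elbow features."""
    feats = ranking.selected
    if not feats:
        raise ValueError("elbow selected no features")
    mtry, ntree = tuned
    sub = train.select_features(feats)
    weights = class_balance_weights(sub.y) if class_weighting else None
    forest = fit_forest(
        sub.X, sub.y, min(mtry, len(feats)), ntree, weights,
        np.random.default_rng(seed), feats,
    )
    forest.threshold = float(np.clip(median(f.threshold for f in folds), 1e-6, 1 - 1e-6))
    return forest
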