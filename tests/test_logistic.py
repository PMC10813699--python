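"""Logistic arm: IRLS fit, forward BIC selection, MRCV, ranking aggregation."""

import numpy as np
import pytest
import statsmodels.api as sm

from nodulefuse.logistic import (
    LRFoldResult, bic, finalize_lr, fit_logistic, forward_bic_select,
    mrcv_lr, rank_features_lr,
)
from nodulefuse.preprocess import robust_standardize
from nodulefuse.simulate import SynthConfig, generate_cohorts


class TestFitLogistic:
    def test_saturated_two_by_two_log_odds_ratio(self):
        x = np.array([1.0] * 10 + [0.0] * 10)
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        m = fit_logistic(x, y)
        assert m.coef[0] == pytest.approx(np.log(16), abs=1e-6)

    def test_null_data_gives_near_zero_slopes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 4))
        y = rng.integers(0, 2, 2000)
        m = fit_logistic(X, y)
        assert np.all(np.abs(m.coef) < 0.1)

    def test_intercept_only_matches_prevalence(self):
        y = np.array([1] * 25 + [0] * 75)
        m = fit_logistic(np.empty((100, 0)), y)
        assert m.predict_proba(np.empty((1, 0)))[0] == pytest.approx(0.25, abs=1e-8)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 3))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7, 0.2])))).astype(int)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert ours.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert np.allclose(ours.coef, ref.params[1:], atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_perfect_separation_triggers_ridge_fallback(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic(x, y)
        assert m.ridged
        assert np.all(np.isfinite(m.coef))


class TestForwardBIC:
    def test_true_feature_added_first_per_bic_scan(self):
        rng = np.random.default_rng(3)
        n = 300
        X = rng.standard_normal((n, 10))
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * X[:, 4]))).astype(int)
        names = [f"f{i}" for i in range(10)]
        sel, path = forward_bic_select(X, y, names)
        # oracle: exhaustive single-feature BIC scan for the first step
        first_bics = []
        for j in range(10):
            m = fit_logistic(X[:, [j]], y)
            first_bics.append(bic(m.loglik, 3, n))
        assert sel[0] == names[int(np.argmin(first_bics))] == "f4"

    def test_infinite_delta_stop_selects_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        y = rng.integers(0, 2, 50)
        sel, path = forward_bic_select(X, y, ["a", "b", "c"], delta_stop=np.inf)
        assert sel == []
        assert len(path) == 1

    def test_pure_noise_rarely_selects_more_than_one(self):
        small = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 10))
            y = rng.integers(0, 2, 200)
            sel, _ = forward_bic_select(X, y, [f"f{i}" for i in range(10)])
            small += len(sel) <= 1
        assert small >= 45

    def test_bic_path_strictly_improving_beyond_stop(self):
        rng = np.random.default_rng(9)
        n = 400
        X = rng.standard_normal((n, 6))
        y = (rng.random(n) < 1 / (1 + np.exp(-(X[:, 0] + 0.8 * X[:, 3])))).astype(int)
        _, path = forward_bic_select(X, y, [f"f{i}" for i in range(6)])
        assert all(a - b > 2.0 for a, b in zip(path, path[1:]))


def _fold(i, feats, bacc, thr=0.5):
    return LRFoldResult(i, feats, [0.0] * (len(feats) + 1), bacc, bacc, thr)


class TestRanking:
    def test_proportional_order_weights(self):
        rk_scores = rank_features_lr([_fold(0, ["A", "B"], 0.8)])
        assert dict(zip(rk_scores.features, rk_scores.scores)) == {
            "A": pytest.approx(0.8), "B": pytest.approx(0.4),
        }

    def test_unselected_feature_scores_zero(self):
        rk = rank_features_lr([_fold(0, ["A"], 0.9)])
        assert "Z" not in rk.features

    def test_two_identical_folds_double_scores(self):
        one = rank_features_lr([_fold(0, ["A", "B", "C"], 0.7)])
        two = rank_features_lr([_fold(0, ["A", "B", "C"], 0.7),
                                _fold(1, ["A", "B", "C"], 0.7)])
        assert np.allclose(two.scores, 2 * one.scores)

    def test_all_empty_folds_rejected(self):
        with pytest.raises(ValueError):
            rank_features_lr([_fold(0, [], 0.5), _fold(1, [], 0.5)])

    def test_first_added_feature_gets_full_weight(self):
        folds = [_fold(i, ["A", "B", "C"], 1.0) for i in range(5)]
        rk = rank_features_lr(folds)
        assert rk.features[0] == "A"
        assert rk.scores[0] == pytest.approx(5.0)   # weight 1 x BAcc 1 x 5 folds


@pytest.fixture(scope="module")
def lr_train_setup():
    cfg = SynthConfig(
        seed=21, n_patients_radiomics=180, n_patients_metabolomics=60,
        n_common=12, n_features_radiomics=25, n_informative_radiomics=5,
        malignant_fraction_radiomics=0.35,
    )
    rad, _, truth = generate_cohorts(cfg)
    std, _ = robust_standardize(rad)
    return std, truth


class TestMRCV:
    def test_repeat_count_and_determinism(self, lr_train_setup):
        std, _ = lr_train_setup
        a = mrcv_lr(std, n_repeats=8, seed=5)
        b = mrcv_lr(std, n_repeats=8, seed=5)
        assert len(a) == 8
        for fa, fb in zip(a, b):
            assert fa.ordered_features == fb.ordered_features
            assert fa.threshold == fb.threshold
            assert fa.bacc_valid == fb.bacc_valid

    def test_informative_features_recur_across_folds(self, lr_train_setup):
        std, truth = lr_train_setup
        folds = mrcv_lr(std, n_repeats=10, seed=1)
        informative = set(truth.informative["radiomics"])
        hit = sum(bool(set(f.ordered_features) & informative) for f in folds)
        assert hit >= 6

    def test_training_bacc_dominates_validation_on_average(self, lr_train_setup):
        std, _ = lr_train_setup
        folds = mrcv_lr(std, n_repeats=10, seed=2)
        gap = np.mean([f.bacc_train for f in folds]) - np.mean([f.bacc_valid for f in folds])
        assert gap >= -0.05

    def test_finalize_produces_thresholded_model(self, lr_train_setup):
        std, truth = lr_train_setup
        folds = mrcv_lr(std, n_repeats=10, seed=3)
        ranking = rank_features_lr(folds)
        model = finalize_lr(std, ranking, folds)
        assert model.features == ranking.selected
        assert 0.0 < model.threshold < 1.0
        probs = model.predict_proba(std)
        assert probs.min() >= 0 and probs.max() <= 1
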