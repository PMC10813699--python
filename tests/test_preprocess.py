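"""Standardization and filtering behavior, including the batch-removal property."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nodulefuse.preprocess import (
    apply_standardizer, correlation_filter, drop_missing_features,
    fit_standardizer, robust_standardize,
)
from nodulefuse.simulate import SynthConfig, generate_cohorts
from nodulefuse.tables import BENIGN, MALIGNANT

from .conftest import make_table


def _benign5_table(extra=None):
    vals = [1.0, 2.0, 3.0, 4.0, 5.0, 3.0, 5.0, 2.0]
    labels = [BENIGN] * 8
    if extra is not None:
        vals = vals + [extra]
        labels = labels + [MALIGNANT]
    return make_table({"f": vals}, labels)


class TestRobustStandardize:
    def test_benign_median_maps_to_zero_and_iqr_scales(self):
        # benign reference {1..5} (plus repeats to satisfy the minimum
        # benign count): median 3, Q1/Q3 by the linear midpoint rule
        tab = make_table({"f": [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]}, [BENIGN] * 10)
        std, ref = robust_standardize(tab)
        med = ref.medians["A"]["f"]
        iqr = ref.iqrs["A"]["f"]
        assert med == 3.0
        assert (5 - med) / iqr == pytest.approx((5 - 3) / 2)

    def test_per_cohort_benign_median_zero_iqr_one(self, small_cohorts):
        rad, _, _ = small_cohorts
        std, _ = robust_standardize(rad)
        ben = std.data[std.data["label"] == BENIGN]
        for _, sub in ben.groupby("cohort"):
            vals = sub[std.feature_names].to_numpy(float)
            assert np.allclose(np.median(vals, axis=0), 0.0, atol=1e-12)
            q1, q3 = np.percentile(vals, [25, 75], axis=0)
            assert np.allclose(q3 - q1, 1.0, atol=1e-12)

    def test_idempotent_on_standardized_data(self, small_cohorts):
        rad, _, _ = small_cohorts
        once, _ = robust_standardize(rad)
        twice, _ = robust_standardize(once)
        assert np.allclose(once.X, twice.X, atol=1e-10)

    def test_zero_iqr_feature_dropped(self):
        tab = make_table(
            {"flat": [1.0] * 9, "ok": list(range(9))},
            [BENIGN] * 8 + [MALIGNANT],
        )
        std, ref = robust_standardize(tab)
        assert ref.dropped == ["flat"]
        assert std.feature_names == ["ok"]

    def test_too_few_benign_rejected(self):
        tab = make_table({"f": [1, 2, 3, 4]}, [BENIGN, BENIGN, MALIGNANT, MALIGNANT])
        with pytest.raises(ValueError, match="benign"):
            fit_standardizer(tab)

    def test_training_reference_applies_to_new_rows(self):
        train = make_table({"f": [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]}, [BENIGN] * 10)
        ref = fit_standardizer(train)
        test = make_table({"f": [3.0, 5.0]}, [MALIGNANT, MALIGNANT])
        out = apply_standardizer(test, ref)
        assert out.data["f"].tolist() == [0.0, 1.0]

    def test_removes_generator_batch_effect(self):
        # post-standardization, benign cohort A vs B differences should be
        # gone for nearly all features (10 seeds)
        fracs = []
        for seed in range(10):
            cfg = SynthConfig(
                seed=seed, n_patients_radiomics=250, n_patients_metabolomics=60,
                n_common=10, n_features_radiomics=30, cohort_b_fraction=0.35,
            )
            rad, _, _ = generate_cohorts(cfg)
            std, _ = robust_standardize(rad)
            ben = std.data[std.data["label"] == BENIGN]
            ps = [
                stats.mannwhitneyu(
                    ben.loc[ben["cohort"] == "A", f], ben.loc[ben["cohort"] == "B", f]
                ).pvalue
                for f in std.feature_names
            ]
            fracs.append(np.mean(np.asarray(ps) > 0.05))
        assert np.mean(fracs) >= 0.95


class TestDropMissing:
    def test_clean_table_unchanged(self, small_cohorts):
        rad, _, _ = small_cohorts
        out, report = drop_missing_features(rad, 0.2)
        assert report == {"dropped_features": [], "removed_samples": []}
        assert out.data.equals(rad.data)

    def test_fully_missing_feature_dropped(self):
        tab = make_table(
            {"gone": [np.nan] * 6, "ok": [1.0, 2, 3, 4, 5, 6]},
            [BENIGN] * 3 + [MALIGNANT] * 3,
        )
        out, report = drop_missing_features(tab, 0.2)
        assert report["dropped_features"] == ["gone"]
        assert out.feature_names == ["ok"]

    def test_sparse_feature_kept_rows_removed(self):
        # 2 of 20 rows missing (10%) under a 20% threshold: keep the
        # feature, remove exactly those rows
        vals = [float(i) for i in range(20)]
        vals[3] = np.nan
        vals[15] = np.nan
        tab = make_table({"f": vals, "g": list(range(20))},
                         [BENIGN] * 10 + [MALIGNANT] * 10)
        out, report = drop_missing_features(tab, 0.2)
        assert report["dropped_features"] == []
        assert sorted(report["removed_samples"]) == ["s15", "s3"]
        assert out.n_samples == 18

    def test_all_features_dropped_is_error(self):
        tab = make_table({"f": [np.nan] * 4}, [BENIGN] * 4)
        with pytest.raises(ValueError):
            drop_missing_features(tab, 0.2)


def _greedy_oracle(frame: pd.DataFrame, threshold: float, prio: dict) -> list[str]:
    """Re-execute the stated greedy rule directly on the correlation matrix."""
    feats = list(frame.columns)
    rho = np.abs(stats.spearmanr(frame.to_numpy()).statistic)
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 0)
    removed = []
    alive = dict.fromkeys(feats, True)
    while True:
        best, pair = 0.0, None
        for a, b in itertools.combinations([f for f in feats if alive[f]], 2):
            r = rho[feats.index(a), feats.index(b)]
            if r > best:
                best, pair = r, (a, b)
        if pair is None or best <= threshold:
            break
        a, b = pair
        loser = a if prio[a] < prio[b] else (b if prio[b] < prio[a] else max(a, b))
        alive[loser] = False
        removed.append(loser)
    return removed


class TestCorrelationFilter:
    def test_duplicate_column_lower_priority_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        tab = make_table({"a": x, "b": x.copy()}, [BENIGN] * 6 + [MALIGNANT] * 6)
        out, removed = correlation_filter(tab, 0.95, {"a": 0.5, "b": 0.2})
        assert removed == ["b"]
        assert out.feature_names == ["a"]

    def test_uncorrelated_table_unchanged(self):
        rng = np.random.default_rng(1)
        tab = make_table(
            {f"f{i}": rng.normal(size=30) for i in range(4)},
            [BENIGN] * 15 + [MALIGNANT] * 15,
        )
        out, removed = correlation_filter(tab, 0.95, {})
        assert removed == []
        assert out.feature_names == tab.feature_names

    def test_matches_greedy_oracle_on_correlated_triple(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        frame = pd.DataFrame({
            "a": base + 0.05 * rng.normal(size=40),
            "b": base + 0.05 * rng.normal(size=40),
            "c": base + 0.05 * rng.normal(size=40),
            "d": rng.normal(size=40),
        })
        prio = {"a": 0.9, "b": 0.5, "c": 0.7, "d": 0.1}
        tab = make_table({k: frame[k].tolist() for k in frame},
                         [BENIGN] * 20 + [MALIGNANT] * 20)
        out, removed = correlation_filter(tab, 0.8, prio)
        assert removed == _greedy_oracle(frame, 0.8, prio)

    def test_output_has_no_pair_above_threshold(self, small_cohorts):
        rad, _, _ = small_cohorts
        out, _ = correlation_filter(rad, 0.6, {})
        rho = np.abs(stats.spearmanr(out.X).statistic)
        rho = np.atleast_2d(rho)
        np.fill_diagonal(rho, 0)
        assert rho.max() <= 0.6

    def test_invalid_threshold(self, small_cohorts):
        rad, _, _ = small_cohorts
        with pytest.raises(ValueError):
            correlation_filter(rad, 1.5, {})
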