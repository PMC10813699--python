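"""End-to-end orchestration: split construction, per-modality arms, fusion, report.

The flow mirrors the study design being modeled:

1. the test set takes a fixed number of benign and malignant patients that
   carry *both* modalities (default 20 + 20); the radiomics test set is
   expanded with additional single-modality patients; everything else
   trains;
2. each modality is cleaned, robustly standardized against the *training*
   benign samples per cohort, screened univariately (training rows only)
   and stripped of highly rank-correlated features;
3. a logistic-regression arm (100 x 70/30 MRCV, forward BIC selection) and
   a random-forest arm (100 x 80/20 MRCV, tuned grid, permutation
   importance) each produce a final model and decision threshold per
   modality;
4. test probabilities are aggregated to patient level (worst nodule for
   radiomics) and the two modalities are fused per model family with the
   Stouffer, mean, max and product rules;
5. every variant is scored (sens/spec/PPV/NPV/F1/BAcc, AUC percent with
   DeLong CI) into a single report table.

No observation of any test patient influences a fitted statistic: the
standardization reference, the univariate priorities, the correlation
filter, the MRCV selections and the thresholds are all computed from
training rows only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import forest, fusion, logistic, metrics, preprocess, selection, univariate
from .simulate import SynthConfig, TruthRecord, generate_cohorts
from .tables import BENIGN, MALIGNANT, OmicsTable

log = logging.getLogger(__name__)

#: Table-2-style radiomics test expansion at the reference cohort size
#: (1086 patients): 82 extra benign + 29 extra malignant patients on top of
#: the 40 dual-modality patients, totalling 122/49.  Scaled proportionally
#: for other cohort sizes.
RADIOMICS_EXTRA_TEST_REFERENCE = (82, 29)
REFERENCE_RADIOMICS_PATIENTS = 1086

CORE_COLUMNS = [
    "lr_radiomics", "lr_metabolomics", "lr_stouffer", "lr_product",
    "rf_radiomics", "rf_metabolomics", "rf_stouffer", "rf_product",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings of a full pipeline run."""

    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    lr_repeats: int = 100
    lr_train_frac: float = 0.70
    rf: forest.RFConfig = field(default_factory=forest.RFConfig)
    corr_threshold: float = 0.95
    integration_methods: tuple[str, ...] = ("stouffer", "mean", "max", "product")
    n_test_common_per_class: int = 20
    max_missing_fraction: float = 0.2
    fast: bool = False

    def resolved_synth(self) -> SynthConfig:
        # one master seed drives everything, including the generator
        return dataclasses.replace(self.synth, seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def fast_run_config(seed: int = 0, synth: SynthConfig | None = None) -> RunConfig:
    """Reduced-cost preset: 25 MRCV repeats and a subsampled RF grid.

    Non-canonical; runs carry a ``fast`` marker in their provenance.
    """
    return RunConfig(
        seed=seed,
        synth=synth or SynthConfig(),
        lr_repeats=25,
        rf=forest.fast_rf_config(n_repeats=25),
        fast=True,
    )


@dataclass
class SplitPlan:
    """Patient-level train/test assignment for both modalities."""

    common_test: list[str]
    radiomics_extra_test: list[str]
    radiomics_train: list[str]
    metabolomics_train: list[str]

    @property
    def radiomics_test(self) -> list[str]:
        return self.common_test + self.radiomics_extra_test

    @property
    def metabolomics_test(self) -> list[str]:
        return self.common_test

    def assert_disjoint(self) -> None:
        for train, test in (
            (self.radiomics_train, self.radiomics_test),
            (self.metabolomics_train, self.metabolomics_test),
        ):
            overlap = set(train) & set(test)
            if overlap:
                raise AssertionError(f"patients straddle train/test: {sorted(overlap)[:5]}")


def make_train_test_split(
    radiomics: OmicsTable,
    metabolomics: OmicsTable,
    config: RunConfig,
    rng: np.random.Generator,
) -> SplitPlan:
    """Build the patient-level split (seeded).

    The common test set draws ``n_test_common_per_class`` benign and
    malignant patients from those present in both modalities; the radiomics
    test set is expanded with extra single-modality patients in proportion
    to the reference design.
    """
    rad_labels = radiomics.patient_labels()
    met_labels = metabolomics.patient_labels()
    common = sorted(set(rad_labels.index) & set(met_labels.index))
    mismatch = [p for p in common if rad_labels[p] != met_labels[p]]
    if mismatch:
        raise ValueError(f"inconsistent patient labels across modalities: {mismatch[:5]}")

    n_per_class = config.n_test_common_per_class
    common_ben = [p for p in common if met_labels[p] == BENIGN]
    common_mal = [p for p in common if met_labels[p] == MALIGNANT]
    if len(common_ben) < n_per_class or len(common_mal) < n_per_class:
        raise ValueError(
            f"need {n_per_class} benign and malignant dual-modality patients, "
            f"have {len(common_ben)}/{len(common_mal)}"
        )
    common_test = sorted(
        list(rng.choice(common_ben, n_per_class, replace=False))
        + list(rng.choice(common_mal, n_per_class, replace=False))
    )

    scale = len(rad_labels) / REFERENCE_RADIOMICS_PATIENTS
    extra_ben_n = int(round(RADIOMICS_EXTRA_TEST_REFERENCE[0] * scale))
    extra_mal_n = int(round(RADIOMICS_EXTRA_TEST_REFERENCE[1] * scale))
    rad_only = sorted(set(rad_labels.index) - set(common))
    pool_ben = [p for p in rad_only if rad_labels[p] == BENIGN]
    pool_mal = [p for p in rad_only if rad_labels[p] == MALIGNANT]
    if len(pool_ben) < extra_ben_n or len(pool_mal) < extra_mal_n:
        raise ValueError(
            f"radiomics expansion needs {extra_ben_n}/{extra_mal_n} extra "
            f"benign/malignant patients, have {len(pool_ben)}/{len(pool_mal)}"
        )
    extra = sorted(
        list(rng.choice(pool_ben, extra_ben_n, replace=False))
        + list(rng.choice(pool_mal, extra_mal_n, replace=False))
    )

    plan = SplitPlan(
        common_test=common_test,
        radiomics_extra_test=extra,
        radiomics_train=sorted(set(rad_labels.index) - set(common_test) - set(extra)),
        metabolomics_train=sorted(set(met_labels.index) - set(common_test)),
    )
    plan.assert_disjoint()
    return plan


@dataclass
class ModalityArm:
    """Everything one modality contributes: models, rankings, predictions."""

    modality: str
    features_used: list[str]
    corr_removed: list[str]
    univariate_train: pd.DataFrame
    lr_folds: list[logistic.LRFoldResult]
    lr_ranking: selection.FeatureRanking
    lr_model: logistic.LRModel
    rf_folds: list[forest.RFFoldResult]
    rf_ranking: selection.FeatureRanking
    rf_tuned: tuple[int, int]
    rf_model: forest.RandomForest
    predictions: dict[str, fusion.PredictionSet]   # keyed "LR"/"RF"
    standardizer: preprocess.StandardizationReference


def _patient_probs(table: OmicsTable, probs: np.ndarray) -> pd.Series:
    """Aggregate row-level probabilities to patient level (worst nodule)."""
    s = pd.Series(probs, index=table.patient_ids.to_numpy())
    return s.groupby(level=0).max()


def _run_arm(
    train: OmicsTable,
    test: OmicsTable,
    config: RunConfig,
    seeds: dict[str, int],
) -> ModalityArm:
    modality = train.modality
    train, _ = preprocess.drop_missing_features(train, config.max_missing_fraction)

    ref = preprocess.fit_standardizer(train)
    train_std = preprocess.apply_standardizer(train, ref)
    test_std = preprocess.apply_standardizer(test, ref)

    uni = univariate.univariate_report(train_std)
    priority = dict(zip(uni["feature"], uni["r_g"].abs()))
    train_f, removed = preprocess.correlation_filter(
        train_std, config.corr_threshold, priority
    )
    feats = train_f.feature_names
    test_f = test_std.select_features(feats)
    log.info("%s: %d features after correlation filter (removed %d)",
             modality, len(feats), len(removed))

    lr_folds = logistic.mrcv_lr(
        train_f, n_repeats=config.lr_repeats, train_frac=config.lr_train_frac,
        seed=seeds["lr"],
    )
    lr_ranking = logistic.rank_features_lr(lr_folds)
    lr_model = logistic.finalize_lr(train_f, lr_ranking, lr_folds)

    rf_folds, rf_tuned = forest.mrcv_rf(train_f, config.rf, seed=seeds["rf"])
    rf_ranking = forest.rank_features_rf(rf_folds, feats)
    rf_model = forest.finalize_rf(
        train_f, rf_ranking, rf_tuned, rf_folds, seed=seeds["rf_final"],
        class_weighting=config.rf.class_weighting,
    )

    predictions = {
        "LR": fusion.PredictionSet(
            _patient_probs(test_f, lr_model.predict_proba(test_f)),
            lr_model.threshold, modality, "LR",
        ),
        "RF": fusion.PredictionSet(
            _patient_probs(test_f, rf_model.predict_proba(test_f)),
            rf_model.threshold, modality, "RF",
        ),
    }
    return ModalityArm(
        modality=modality, features_used=feats, corr_removed=removed,
        univariate_train=uni,
        lr_folds=lr_folds, lr_ranking=lr_ranking, lr_model=lr_model,
        rf_folds=rf_folds, rf_ranking=rf_ranking, rf_tuned=rf_tuned,
        rf_model=rf_model, predictions=predictions, standardizer=ref,
    )


@dataclass
class PipelineResult:
    report: pd.DataFrame
    confusions: dict[str, metrics.ConfusionMatrix]
    roc_points: dict[str, tuple[np.ndarray, np.ndarray]]
    arms: dict[str, ModalityArm]
    integrated: dict[str, fusion.IntegratedPrediction]
    split: SplitPlan
    truth: TruthRecord | None
    provenance: dict

    def write_outputs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report.csv")
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1))
        for name, arm in self.arms.items():
            arm.univariate_train.to_csv(out / f"univariate_{name}.csv", index=False)
            (out / f"preprocess_{name}.json").write_text(json.dumps({
                "standardization": arm.standardizer.to_dict(),
                "correlation_removed": arm.corr_removed,
            }))
            pd.DataFrame({
                "feature": arm.lr_ranking.features, "score": arm.lr_ranking.scores,
            }).to_csv(out / f"ranking_lr_{name}.csv", index=False)
            pd.DataFrame({
                "feature": arm.rf_ranking.features, "score": arm.rf_ranking.scores,
            }).to_csv(out / f"ranking_rf_{name}.csv", index=False)
            (out / f"model_lr_{name}.json").write_text(json.dumps(arm.lr_model.to_dict()))
            (out / f"model_rf_{name}.json").write_text(
                json.dumps(arm.rf_model.to_dict() | {"threshold": arm.rf_model.threshold})
            )
        cms = {
            k: {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
            for k, c in self.confusions.items()
        }
        (out / "confusions.json").write_text(json.dumps(cms, indent=1))
        (out / "integrated_predictions.json").write_text(json.dumps({
            k: {
                "method": v.method, "threshold": v.threshold,
                "sources": list(v.sources),
                "probabilities": {p: float(x) for p, x in v.probabilities.items()},
            }
            for k, v in self.integrated.items()
        }, indent=1))
        (out / "roc_points.json").write_text(json.dumps({
            k: {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
            for k, (fpr, tpr) in self.roc_points.items()
        }))


def run_pipeline(
    config: RunConfig,
    tables: tuple[OmicsTable, OmicsTable] | None = None,
    truth: TruthRecord | None = None,
) -> PipelineResult:
    """Execute the full two-modality analysis.

    ``tables`` (radiomics, metabolomics) may be supplied to run on external
    data; otherwise the synthetic generator produces them from the master
    seed.  Reruns with an identical config are identical.
    """
    master = np.random.default_rng(config.seed)
    stage_seeds = {name: int(master.integers(2**31)) for name in
                   ("split", "rad_lr", "rad_rf", "rad_rf_final",
                    "met_lr", "met_rf", "met_rf_final")}

    if tables is None:
        radiomics, metabolomics, truth = generate_cohorts(config.resolved_synth())
    else:
        radiomics, metabolomics = tables

    split = make_train_test_split(
        radiomics, metabolomics, config, np.random.default_rng(stage_seeds["split"])
    )

    arms: dict[str, ModalityArm] = {}
    for table, prefix in ((radiomics, "rad"), (metabolomics, "met")):
        train = table.for_patients(
            split.radiomics_train if prefix == "rad" else split.metabolomics_train
        )
        test = table.for_patients(
            split.radiomics_test if prefix == "rad" else split.metabolomics_test
        )
        arms[table.modality] = _run_arm(
            train, test, config,
            seeds={"lr": stage_seeds[f"{prefix}_lr"], "rf": stage_seeds[f"{prefix}_rf"],
                   "rf_final": stage_seeds[f"{prefix}_rf_final"]},
        )

    rad_arm = arms["radiomics"]
    met_arm = arms["metabolomics"]

    # patient-level truth
    rad_patient_labels = radiomics.patient_labels()
    met_patient_labels = metabolomics.patient_labels()
    all_labels = pd.concat([rad_patient_labels, met_patient_labels])
    all_labels = all_labels[~all_labels.index.duplicated()]

    integrated: dict[str, fusion.IntegratedPrediction] = {}
    columns: dict[str, tuple[pd.Series, float]] = {}
    for family in ("LR", "RF"):
        fam = family.lower()
        for arm, name in ((rad_arm, "radiomics"), (met_arm, "metabolomics")):
            ps = arm.predictions[family]
            columns[f"{fam}_{name}"] = (ps.probabilities, ps.threshold)
        for method in config.integration_methods:
            integ = fusion.integrate_predictions(
                rad_arm.predictions[family], met_arm.predictions[family], method
            )
            integrated[f"{fam}_{method}"] = integ
            columns[f"{fam}_{method}"] = (integ.probabilities, integ.threshold)

    report_cols: dict[str, dict] = {}
    confusions: dict[str, metrics.ConfusionMatrix] = {}
    roc_points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (probs, thr) in columns.items():
        y = (all_labels[probs.index] == MALIGNANT).to_numpy(int)
        rep = metrics.full_report(probs.to_numpy(), y, thr)
        report_cols[name] = rep.rounded()
        confusions[name] = metrics.confusion(
            (probs.to_numpy() >= thr).astype(int), y
        )
        roc_points[name] = metrics.roc_curve(probs.to_numpy(), y)

    report = pd.DataFrame(report_cols)
    report.loc["auc_ci_low"] = [report_cols[c]["auc_ci"][0] for c in report.columns]
    report.loc["auc_ci_high"] = [report_cols[c]["auc_ci"][1] for c in report.columns]
    report = report.drop(index="auc_ci")

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "lr_repeats": config.lr_repeats,
        "rf_repeats": config.rf.n_repeats,
        "rf_grid": {"mtry": list(config.rf.mtry_grid), "ntree": list(config.rf.ntree_grid)},
        "mode": "fast (non-canonical reduced repeats/grid)" if config.fast else "canonical",
        "n_train_rows": {
            "radiomics": int(radiomics.for_patients(split.radiomics_train).n_samples),
            "metabolomics": int(metabolomics.for_patients(split.metabolomics_train).n_samples),
        },
        "n_test_patients": {
            "radiomics": len(split.radiomics_test),
            "metabolomics": len(split.metabolomics_test),
            "common": len(split.common_test),
        },
    }
    return PipelineResult(
        report=report, confusions=confusions, roc_points=roc_points,
        arms=arms, integrated=integrated, split=split, truth=truth,
        provenance=provenance,
    )
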