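"""The logistic-regression arm: MRCV forward-BIC selection and final model.

100 random 70/30 patient-stratified splits; in each, forward selection adds
features while BIC improves by more than 2, and a probability threshold
maximizes balanced accuracy on the validation patients.  Features are
ranked by proportional order of addition weighted by validation BAcc; an
elbow cutoff picks the working set for the final full-training-set fit.

A reduced setup (fewer patients/repeats) keeps this example quick.
"""

from nodulefuse import SynthConfig, generate_cohorts
from nodulefuse.logistic import finalize_lr, mrcv_lr, rank_features_lr
from nodulefuse.preprocess import robust_standardize

cfg = SynthConfig(seed=2, n_patients_radiomics=300, n_features_radiomics=60)
radiomics, _, truth = generate_cohorts(cfg)
standardized, _ = robust_standardize(radiomics)

folds = mrcv_lr(standardized, n_repeats=20, seed=0)
sizes = [len(f.ordered_features) for f in folds]
print(f"20 MRCV repeats: model sizes {min(sizes)}..{max(sizes)}, "
      f"mean validation BAcc "
      f"{sum(f.bacc_valid for f in folds) / len(folds):.3f}")

ranking = rank_features_lr(folds)
print(f"elbow keeps {ranking.elbow_k} of {len(ranking.features)} ranked features:")
for name, score in zip(ranking.selected, ranking.scores):
    mark = "*" if name in truth.informative["radiomics"] else " "
    print(f"  {mark} {name}  score {score:.2f}")

model = finalize_lr(standardized, ranking, folds)
print(f"final model: {len(model.features)} features, "
      f"threshold {model.threshold:.3f} (median of fold thresholds)")

# Starred features are truth-informative; the score is the summed
# (proportional-order x validation-BAcc) credit across repeats.
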