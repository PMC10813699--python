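# Methods

`nodulefuse` implements a two-modality late-fusion analysis for
discriminating benign from malignant lung nodules found in low-dose CT
(LDCT) screening: per-modality classifiers — one on precomputed radiomic
feature tables (one row per nodule), one on serum-metabolomics
concentration tables (one row per patient) — whose test-set probabilities
and decision thresholds are then combined by four integration rules.  This
note records the model, the defaults and the design decisions, in the
package's own terms.

## Data model

An `OmicsTable` is a rectangular feature table with metadata columns
`sample_id, patient_id, cohort, label` (`label` is `benign`/`malignant`;
malignant is the positive class everywhere).  Radiomics tables may carry
several rows per patient; a patient counts as malignant as soon as one of
their nodules is (screening participants can carry benign and malignant
nodules simultaneously).  All train/validation/test splitting happens at
the patient level, stratified by this patient-level label, so no patient's
nodules ever straddle a split.

## Preprocessing

**Robust benign-referenced standardization.** Per feature and acquisition
cohort, `x' = (x − median) / IQR`, with median and IQR computed on the
*benign* samples of that cohort.  Quantiles use the linear-interpolation
(type-7) rule, so the IQR of `{1,2,3,4,5}` is `4 − 2 = 2`.  Referencing the
benign class inside each cohort doubles as batch correction: after the
transform, benign samples have median 0 and IQR 1 in every cohort, and the
generator's cohort shift disappears (≥95% of features show no cohort
difference among benign samples afterwards).  For test data the reference
statistics are always the ones fitted on training benign samples —
test-referenced scaling would leak test information into the transform.
Features with zero benign IQR in any cohort are degenerate and dropped with
a warning.

**Missingness.** Features missing in more than a configurable fraction of
rows (default 0.2) are dropped; remaining rows with missing entries are
removed, and both removals are reported.

**Correlation filter.** Before modeling, highly rank-correlated features
are removed greedily: while any pair exceeds `|Spearman ρ| > 0.95`
(Spearman because the raw features are strongly skewed), the pair with the
largest `|ρ|` is visited and its member with the smaller univariate effect
size `|r_g|` is removed (ties: the lexicographically later name).

## Univariate screening

Each feature is compared benign-vs-malignant with the Mann–Whitney test
(normality is screened with Shapiro–Wilk first, subsampled at 5000
observations; the features are grossly non-normal, which is why the
pipeline is rank-based).  `U` counts wins of the first group (benign in
reports), the p-value is exact for `min(n1, n2) ≤ 8` without ties and uses
the tie-corrected continuity-corrected normal approximation otherwise, and
the effect size is the rank-biserial correlation

    r_g = 1 − 2U / (n1·n2),

so `r_g > 0` means elevated in malignant.  Screening runs at the
observation level (all nodules), matching how the per-feature statistics
are defined.  Multiplicity is controlled with Benjamini–Hochberg q-values;
`direction` is the sign of the malignant-minus-benign median difference.

## Model arms

Both arms use **multiple random cross-validation (MRCV)**: repeated
stratified patient-grouped random splits of the training table (100
repeats canonically).  Thresholds and balanced accuracies are always
computed on *patient-pooled* probabilities (worst-nodule rule, below),
because the clinical decision is per patient; estimating the threshold at
nodule level and applying it to patient-maxima would systematically
inflate sensitivity.

**Logistic regression (70/30 splits).** Per repeat: forward stepwise
selection starting from the intercept-only model; each step fits every
single-feature addition by IRLS (score tolerance 1e-8, max 100 iterations;
suspected perfect separation triggers a ridge-1e-6 refit with a warning)
and adds the lowest-BIC candidate if the improvement exceeds 2 BIC units
(`BIC = k·ln n − 2·lnL`, k counting the intercept; ties break
lexicographically).  The fold records the addition order, the BIC path,
train/validation balanced accuracy, and the validation threshold.
Features are then ranked across repeats: the feature added at position
`j` of an `m`-feature fold earns weight `(m − j + 1)/m`, multiplied by the
fold's validation BAcc and summed over folds.  An elbow cutoff picks the
final feature set; the final model is refit on the full training table and
its threshold is the median of the fold thresholds.

**Random forest (80/20 splits).** Trees are fully grown Gini CART trees
(no depth limit, minimum leaf 1) fit on bootstrap samples drawn with
class-balancing probabilities `w_i ∝ N/(2·N_class(i))`, so both classes
contribute half the expected bootstrap mass regardless of the 75/25
imbalance.  A `(mtry, ntree)` grid (canonically mtry 5..30, ntree
100/500/1000/2000) is tuned per repeat by validation BAcc (ties prefer
smaller ntree, then smaller mtry).  Per-feature importance is the
out-of-bag permutation importance of the best fit: per tree,
`Δ = OOB accuracy − OOB accuracy after permuting the feature within the
OOB rows`, averaged over trees and normalized by its standard error
(`mean/ (sd/√ntree)`; sd = 0 ⇒ 0).  The OOB accuracy here is the
*weighted* fraction correct under the training weights: trees grown on
balanced bootstraps over-call the minority class on raw imbalanced OOB
rows, and with plain accuracy the destruction of a genuinely informative
feature can *raise* the score (we reproduced the same inversion with R's
`randomForest` under balanced `sampsize`); weighting the accuracy like the
training objective keeps the sign meaningful.  Rankings average the
importance across repeats; elbow, refit and median threshold as in the LR
arm.  Importance z-scores scale with `√ntree`, so the reduced "fast" grid
uses a single `(mtry 15, ntree 500)` point rather than the canonical
grid's noisiest corner (`ntree = 100`).

**Elbow cutoff.** On a descending score curve, deviations from the chord
joining the first and last points are examined.  A plateau-then-drop curve
bulges above the chord and the knee is the point of maximum positive
deviation (kept); a steep-drop-then-tail curve sags below the chord and
the point of maximum sag is the first tail point (everything before it is
kept).  Ties go to the smallest count; a collinear curve keeps everything;
with only two scores, the first is kept.

**Threshold.** The candidate cutoffs are midpoints of consecutive distinct
probabilities plus 0.5; the smallest candidate maximizing balanced
accuracy of `prob ≥ t → malignant` wins (favoring sensitivity).

**Patient pooling.** A patient's probability is the maximum over their
nodules — the worst-nodule rule, matching how a radiologist would act on
the most suspicious finding.

## Late fusion

Per model family, the radiomics and metabolomics `PredictionSet`s are
combined on their common patients with four rules, each applied
identically to probabilities and thresholds:

* **Stouffer**: `Φ((probit(p₁) + probit(p₂))/√2)`, unweighted, with
  symmetric clipping at 1e-6 before the probit (the method is defined for
  normal scores; the probit transform takes calibrated probabilities
  there, and both interpretations coincide at 0.5);
* **mean**, **max**, **product**: elementwise.

All four rules are monotone in each argument.  The product rule is not
invariant under an additive recalibration of probabilities and thresholds
(mean and max are); this is a property of the scheme, not a defect, and is
asserted as such in the tests.

## Evaluation

Metrics are confusion-derived (sensitivity, specificity, PPV, NPV, F1,
balanced accuracy) at the model's threshold, with AUC from the rank
(Mann–Whitney) statistic with midrank ties — identical to the trapezoidal
area under the empirical ROC — and a DeLong placement-value 95% CI.
Reports round half-away-from-zero to two decimals and print AUC in
percent.  Radiomics models are evaluated on the expanded radiomics test
patients; metabolomics and all integrations on the dual-modality test
patients.

## Synthetic cohorts

The generator emulates the screening-study structure end to end: 1086
radiomics patients (~25% malignant at patient level; `1 + Poisson(0.2)`
nodules each; malignant patients have at least one malignant nodule, other
nodules are coin flips, so mixed-label patients occur) across two cohorts
with an additive-location/multiplicative-scale batch shift on cohort "B";
246 metabolomics patients (50/50, single cohort); 40 patients in both
modalities with consistent labels, half per class.  Features are
log-normal (log-sd 0.5) under a block-equicorrelated Gaussian copula
(ρ = 0.7, noise blocks of 10).  Informative features (10 per modality)
receive an additive class shift on the raw scale, calibrated by monotone
root-finding on the quadrature-computed exceedance probability so that the
expected rank-biserial equals the target (0.6 radiomics, 0.26
metabolomics); shift directions are drawn per cluster.

Two structural choices matter and were fixed after explicit diagnosis:

* informative features never share a copula block with noise features —
  otherwise noise features become jointly class-dependent proxies and the
  generator's ground truth stops being the truth;
* informative features form correlated *clusters of 3* rather than one
  exchangeable cluster of 10: in a large exchangeable cluster each
  member's unique signal contribution vanishes, permutation importance
  then measures only the overfitting penalty (systematically negative
  z-scores), and no per-feature selection procedure could recover the set.
  Small clusters keep the correlated-informative pattern while leaving
  recovery well-posed.

The modalities are conditionally independent given the patient label by
default (`shared_latent_weight = 0` mixes in a per-patient latent factor
when sensitivity analyses want cross-modality dependence).

What the generator does **not** emulate: real radiomic feature families
and their heterogeneous effect sizes, assay-specific missingness and
batch-correction artifacts, clinical covariates, or any dependence of
nodule count on malignancy.  Passing recovery tests therefore show the
*procedure* behaves as designed under its assumptions, not that it would
reach the same operating points on clinical data.

## Problem sizes in tests and the acceptance script

Fast mode (`fast_run_config`) uses 25 MRCV repeats and the single-point RF
grid; recovery checks run it on a 400-patient radiomics cohort (scaled
from 1086 to keep a ten-seed sweep within minutes on one CPU) with the
study-size 246-patient metabolomics cohort, whose weak 0.26 effects need
the full n.  The fusion property is evaluated on binormal modalities with
Bayes-calibrated posteriors (AUC 0.83/0.60) at 1000 patients per class ×
20 replicates, large enough that the comparison reflects the combination
rules rather than sampling noise.  Null FDR checks use 150-patient,
100-feature null cohorts × 20 seeds.

## Known limitations

* Forward BIC selection under correlated informative clusters picks one
  representative per cluster; the final LR model is parsimonious and its
  selected set should be read as cluster representatives, not an
  exhaustive list of informative features (the two arms' selected sets
  overlap only partially, as expected).
* Permutation importance remains masked under strong within-cluster
  correlation; the grid tie-break toward smaller ntree can hand the
  ranking its noisiest importance estimates when validation BAcc ties.
* Thresholds fused by the product rule shrink toward zero by
  construction; combined decisions are therefore more sensitive than
  either source alone.
* DeLong intervals collapse at AUC = 1 and are reported as degenerate
  rather than widened.
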