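"""Robust benign-referenced standardization and univariate screening.

Features are scaled per cohort to the benign median/IQR (removing the batch
shift), then each feature is tested benign-vs-malignant with the
Mann-Whitney test; the rank-biserial correlation r_g serves as effect size
and Benjamini-Hochberg q-values control the false discovery rate.
"""

from nodulefuse import SynthConfig, generate_cohorts
from nodulefuse.preprocess import correlation_filter, robust_standardize
from nodulefuse.univariate import univariate_report

radiomics, _, truth = generate_cohorts(SynthConfig(seed=1))
standardized, reference = robust_standardize(radiomics)

report = univariate_report(standardized)
n_sig = (report["q"] < 0.05).sum()
print(f"{n_sig} of {len(report)} radiomic features significant at FDR < 0.05")
print(f"up in malignant: {(report.loc[report.q < 0.05, 'direction'] == 'up').sum()}, "
      f"down: {(report.loc[report.q < 0.05, 'direction'] == 'down').sum()}")
print("\nstrongest effects (|r_g|):")
print(report.head(5)[["feature", "r_g", "q", "direction"]].to_string(index=False))

priority = dict(zip(report["feature"], report["r_g"].abs()))
filtered, removed = correlation_filter(standardized, 0.95, priority)
print(f"\ncorrelation filter (|rho| > 0.95): removed {len(removed)} features, "
      f"{len(filtered.feature_names)} remain")
print(f"truth informative among significant: "
      f"{len(set(truth.informative['radiomics']) & set(report.loc[report.q < 0.05, 'feature']))}/10")

# The top-|r_g| features should be exactly the generator's informative set;
# q-values near zero reflect the strong (r_g ~ 0.6) radiomics effects.
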