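"""Generate synthetic two-modality screening cohorts and inspect their structure.

The generator emulates a lung-cancer screening study: a large radiomics
cohort (one row per nodule, two acquisition cohorts with a batch shift,
~75/25 benign/malignant patients) and a smaller balanced serum-metabolomics
cohort (one row per patient), with a shared subset of patients measured in
both.  A truth record carries the informative feature names for
parameter-recovery checks.
"""

from nodulefuse import SynthConfig, generate_cohorts

radiomics, metabolomics, truth = generate_cohorts(SynthConfig(seed=1))

print(f"radiomics:     {radiomics.n_samples} nodule rows, "
      f"{radiomics.patient_ids.nunique()} patients, "
      f"{len(radiomics.feature_names)} features")
print(f"metabolomics:  {metabolomics.n_samples} patient rows, "
      f"{len(metabolomics.feature_names)} features")
common = set(radiomics.patient_ids) & set(metabolomics.patient_ids)
print(f"dual-modality patients: {len(common)}")
mal_frac = (radiomics.patient_labels() == "malignant").mean()
print(f"radiomics malignant patient fraction: {mal_frac:.2f}")
print(f"informative radiomics features: {truth.informative['radiomics']}")

# The malignant fraction reflects the emulated screening prevalence (~25%),
# and the listed features are the only ones whose distribution depends on
# the nodule label -- everything downstream tries to rediscover them.
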