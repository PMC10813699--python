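import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nodulefuse.simulate import SynthConfig, generate_cohorts
from nodulefuse.tables import OmicsTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: small-but-realistic generator settings shared by cross-module tests
SMALL_SYNTH = SynthConfig(
    seed=11,
    n_patients_radiomics=220,
    n_patients_metabolomics=120,
    n_common=24,
    n_features_radiomics=40,
    n_features_metabolomics=50,
    n_informative_radiomics=5,
    n_informative_metabolomics=5,
    malignant_fraction_radiomics=0.3,
)


@pytest.fixture(scope="session")
def small_cohorts():
    return generate_cohorts(SMALL_SYNTH)


@pytest.fixture(scope="session")
def default_cohorts():
    return generate_cohorts(SynthConfig(seed=1))


def make_table(values: dict[str, list], labels: list[str], cohort: str | list = "A",
               modality: str = "test") -> OmicsTable:
    """Hand-build a tiny OmicsTable from per-feature value lists."""
    n = len(labels)
    frame = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "patient_id": [f"p{i}" for i in range(n)],
        "cohort": cohort if isinstance(cohort, list) else [cohort] * n,
        "label": labels,
    })
    for name, vals in values.items():
        frame[name] = vals
    return OmicsTable(frame, modality)
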