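import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from hyposmia import (
    Cohort,
    ConversionTable,
    NormativeModel,
    convert_scores,
    derive_centile_cutoffs,
    generate_pd_cohort,
    sample_reference,
)
from hyposmia.normative import PDGeneratorConfig


@pytest.fixture(scope="session")
def conversion():
    return ConversionTable.default()


@pytest.fixture(scope="session")
def normative_model():
    return NormativeModel()


@pytest.fixture(scope="session")
def reference(normative_model):
    return sample_reference(n=100_000, model=normative_model, seed=11)


@pytest.fixture(scope="session")
def cutoffs(reference):
    return derive_centile_cutoffs(reference)


@pytest.fixture(scope="session")
def tracking_cohort(conversion):
    """Synthetic Tracking-like cohort (n=1674, default generator, fixed seed)."""
    return convert_scores(generate_pd_cohort(PDGeneratorConfig(seed=101)), conversion)


@pytest.fixture()
def tiny_cohort():
    return Cohort(
        pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "age_at_test": [65.0, 45.0, 70.0],
                "gender": ["male", "female", "male"],
                "disease_duration": [2.0, 1.0, np.nan],
                "test_kind": ["UPSIT40", "SS16", "UPSIT40"],
                "raw_score": [20, 12, 30],
            }
        )
    )
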