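import pandas as pd
import pytest

from cqtriage import CovariateConfig, GroupEffectConfig, generate_cohort
from cqtriage.datasets import (
    CLASSIFIER1_PAIRS,
    recover_reference_weights,
    reference_cohort,
    reference_df,
)


@pytest.fixture(scope="session")
def effects():
    return GroupEffectConfig.default()


@pytest.fixture(scope="session")
def cohort_and_covariates(effects):
    return generate_cohort(effects, CovariateConfig(), seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_and_covariates):
    return cohort_and_covariates[0]


@pytest.fixture(scope="session")
def ref_cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def ref_classifier():
    clf, residual = recover_reference_weights()
    assert residual < 0.05
    return clf


@pytest.fixture(scope="session")
def ref_df() -> pd.Series:
    return reference_df()


@pytest.fixture(scope="session")
def classifier1_pairs():
    return CLASSIFIER1_PAIRS
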