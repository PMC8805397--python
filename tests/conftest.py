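import numpy as np
import pandas as pd
import pytest

from nivstack.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """300-patient cohort with defaults; shared across tests."""
    return generate_cohort(CohortSpec(n_patients=300, seed=123))


@pytest.fixture(scope="session")
def messy_cohort() -> pd.DataFrame:
    """Cohort with missingness and planted outliers."""
    return generate_cohort(
        CohortSpec(n_patients=400, seed=7, missing_rate=0.08, outlier_rate=0.02)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def overlap_Xy():
    """Imbalanced two-class overlap: 90% majority at origin, 10%
    minority shifted by ~1 SD."""
    r = np.random.default_rng(99)
    n_maj, n_min, d = 450, 50, 5
    X = np.vstack(
        [r.standard_normal((n_maj, d)), r.standard_normal((n_min, d)) + 1.0]
    )
    y = np.array([0] * n_maj + [1] * n_min)
    return X, y
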