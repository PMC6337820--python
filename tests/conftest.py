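import warnings

import numpy as np
import pandas as pd
import pytest

from jointbone.synthetic import CohortConfig, simulate_cohort

warnings.filterwarnings("ignore", category=RuntimeWarning)

COVS = ["age", "sex", "extra_mets"]


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (n=147, study-like missingness)."""
    return simulate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Complete-data cohort for estimator checks (no missingness)."""
    cfg = CohortConfig(
        n_patients=200, seed=7, dropout_prob=0.0, intermittent_miss_prob=0.0
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def tiny_survival():
    """Three-record table with a hand-computable Kaplan-Meier curve."""
    return pd.DataFrame(
        {"id": [1, 2, 3], "time_obs": [1.0, 1.5, 2.0], "status": [1, 0, 1]}
    )
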