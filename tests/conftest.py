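import numpy as np
import pandas as pd
import pytest

from milktriad.preprocess import preprocess_visit_table
from milktriad.synthetic import CohortParams, generate_cohort

NO_DROPOUT = {"V1": 0.0, "V2": 1.0, "V3": 1.0, "V4": 1.0}


@pytest.fixture(scope="session")
def structured_cohort():
    """Mid-size cohort with a known nonzero mediation structure, no
    censoring and no dropout: the workhorse for recovery checks."""
    params = CohortParams(
        n_dyads=300, seed=42, a1=0.5, b1=0.8, c1_prime=0.2,
        lod_censor=False, dropout=dict(NO_DROPOUT),
    )
    visits, feed_logs, truth = generate_cohort(params)
    return preprocess_visit_table(visits), feed_logs, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no structure anywhere (all effects zero)."""
    params = CohortParams(
        n_dyads=300, seed=7, lod_censor=False, dropout=dict(NO_DROPOUT)
    )
    visits, feed_logs, truth = generate_cohort(params)
    return preprocess_visit_table(visits), feed_logs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
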