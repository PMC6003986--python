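import numpy as np
import pandas as pd
import pytest

from adprog import CohortConfig, default_schema, simulate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 300-patient cohort with the packaged defaults."""
    return simulate_cohort(CohortConfig(n_patients=300, seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully observed high-fidelity cohort for learning checks."""
    return simulate_cohort(
        CohortConfig(n_patients=300, seed=7, p_fid=1.0, inject_missing=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
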