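from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import cohortmatch.datasets
from cohortmatch.datasets import load_trial_records, load_trial_table, published_reference
from cohortmatch.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def packaged_table_path() -> Path:
    return Path(cohortmatch.datasets.__file__).parent / "data" / "included_trials.csv"


@pytest.fixture(scope="session")
def trial_table() -> pd.DataFrame:
    return load_trial_table()


@pytest.fixture(scope="session")
def trial_records():
    records, issues = load_trial_records()
    assert not issues
    return records


@pytest.fixture(scope="session")
def overall_reference():
    return published_reference()


@pytest.fixture(scope="session")
def synthetic_cohort() -> pd.DataFrame:
    """Default synthetic reference cohort (n = 2792, fixed seed)."""
    return generate_cohort(CohortConfig(seed=20240901))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
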