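import numpy as np
import pytest

from sterilopt.data import load_treatment_tables, observation_table_from_records
from sterilopt.simulate import ReplicateConfig, expand_replicates


@pytest.fixture(scope="session")
def records():
    return load_treatment_tables()


@pytest.fixture(scope="session")
def mean_table(records):
    """One row per printed treatment, responses = printed means."""
    return observation_table_from_records(records)


@pytest.fixture(scope="session")
def replicated_table(records):
    """The canonical replicate expansion: 8 replicates per treatment."""
    return expand_replicates(records, ReplicateConfig(replicates_per_treatment=8, seed=1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
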