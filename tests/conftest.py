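import numpy as np
import pytest

from comornet import PopulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic cohort shared by read-only tests."""
    patients, records = generate_dataset(PopulationConfig(n_patients=300, seed=7), seed=7)
    return patients, records


@pytest.fixture()
def rng():
    return np.random.default_rng(20318)
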