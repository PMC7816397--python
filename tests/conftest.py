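import numpy as np
import pytest

from allomix import GeneratorConfig, generate_counts
from allomix.qc import filter_counts, normalize_log


@pytest.fixture(scope="session")
def small_data():
    """Default-noise experiment at reduced depth, shared across tests."""
    return generate_counts(GeneratorConfig(seed=7, cells_per_donor_per_lane=250))


@pytest.fixture(scope="session")
def small_norm(small_data):
    return normalize_log(filter_counts(small_data.adata))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
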