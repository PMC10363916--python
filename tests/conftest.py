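import numpy as np
import pytest

from netprio.synthetic import SyntheticConfig, generate_universe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_genes=2000, n_traits=3, n_databases=2, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_universe(small_config)
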