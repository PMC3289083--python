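import numpy as np
import pytest

from atpsite.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared across tests (12 short chains)."""
    config = SimConfig(n_chains=12, length_mean=150, length_sd=10, seed=7)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_null_dataset():
    """Null construction: no PSSM shift, no motif — labels carry no signal."""
    config = SimConfig(n_chains=12, length_mean=150, length_sd=10,
                       pssm_delta=0.0, motif=None, conservation_delta=0.0,
                       seed=7)
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
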