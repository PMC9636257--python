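import numpy as np
import pytest

from sedapipe.filtering import run_cascade
from sedapipe.synthetic_data import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_samples=24,
        n_extraction_controls=3,
        n_pcr_controls=3,
        n_taxa=25,
        replicates=8,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    """(raw table, traits, truth) at a reduced but structurally complete scale."""
    return simulate_community(small_config)


@pytest.fixture(scope="session")
def small_retained(small_community):
    table, _, _ = small_community
    retained, reports = run_cascade(table)
    return retained, reports


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
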