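import numpy as np
import pytest
from hypothesis import settings

from dipnet import simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        n_genes=400, n_lincrna=5, n_pseudogene_families=4,
        n_proteins=12, n_peptides=18, frac_reactivated=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def sim_data(small_config):
    return simulate.generate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
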