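import pytest

from methylrescue.binning import compute_bin_matrix
from methylrescue.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully-featured study configuration for structural tests."""
    return SimulationConfig(
        seed=3,
        n_islands=250,
        n_chromosomes=2,
        n_genes=200,
        n_go_terms=12,
        genes_per_term=15,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_bin_matrix(small_study):
    return compute_bin_matrix(small_study.methylome.calls, small_study.methylome.sample_sheet)


@pytest.fixture(scope="session")
def default_study():
    """The full-size default simulation (5,000 bins), shared across tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_bin_matrix(default_study):
    return compute_bin_matrix(default_study.methylome.calls, default_study.methylome.sample_sheet)
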