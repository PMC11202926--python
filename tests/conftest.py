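import pytest

from barcodekit.distances import distance_matrix
from barcodekit.simulate import SimulationConfig, simulate

SMALL = SimulationConfig(
    n_species=5, specimens_per_species=4, n_genera=3, n_families=2, seed=11
)


@pytest.fixture(scope="session")
def small_sim():
    """One modest synthetic dataset shared across read-only tests."""
    return simulate(SMALL)


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    return distance_matrix(small_sim.records)


@pytest.fixture(scope="session")
def small_species(small_sim):
    return {r.specimen_id: r.morphological_label for r in small_sim.records}
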