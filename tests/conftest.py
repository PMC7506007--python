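import numpy as np
import pytest

from hybgen import simulate as sim


@pytest.fixture(scope="session")
def small_map():
    """Six autosomes + Z, enough to exercise multi-chromosome logic cheaply."""
    return sim.default_map(n_autosomes=6)


@pytest.fixture(scope="session")
def full_map():
    return sim.default_map()


@pytest.fixture(scope="session")
def small_panel(small_map):
    return sim.simulate_species_panels(small_map, sites_per_chrom=1200,
                                       frac_diagnostic=0.8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
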