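import numpy as np
import pytest

from lncpipe.simulate import SimulationConfig, simulate_study


SMALL_CONFIG = dict(
    n_chromosomes=2,
    chrom_length_bp=1_200_000,
    n_coding_genes=60,
    n_lnc_genes=40,
    n_cis_pairs=4,
    n_equal_to_coding=4,
    n_equal_to_lnc=4,
    n_per_code=4,
    n_j_coding=4,
    n_duplicate_pairs=2,
)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared by read-only tests."""
    return simulate_study(SimulationConfig(seed=42, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_study():
    """One default-size synthetic study (the emulated design)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
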