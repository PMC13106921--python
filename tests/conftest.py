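import numpy as np
import pytest

from ucepi.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_loci():
    """A modest synthetic dataset for fast end-to-end checks."""
    return simulate_dataset(SimConfig(k=60, n=8, flank=200, seed=5))


@pytest.fixture(scope="session")
def messy_loci():
    """Synthetic data with missing individuals and ragged edges."""
    return simulate_dataset(
        SimConfig(k=80, n=8, flank=200, missing_rate=0.25, edge_trim_max=40, seed=9)
    )


@pytest.fixture(scope="session")
def standard_loci():
    """The standard validation conditions: 2000 loci, 10 individuals,
    750 bp flanks, theta=0.005, beta=10, gamma=0.009."""
    return simulate_dataset(SimConfig(seed=20260920))


@pytest.fixture(scope="session")
def standard_stats(standard_loci):
    from ucepi.sites import dataset_site_stats

    return dataset_site_stats(standard_loci)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
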