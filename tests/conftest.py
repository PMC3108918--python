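import numpy as np
import pytest

from mdrld.disease import CaseControlDataset
from mdrld.io import ExperimentConfig, simulate_and_select_pools
from mdrld.ld import HaplotypePool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pool(rng):
    """50 haplotypes x 20 loci, independent columns with mixed frequencies."""
    freqs = rng.uniform(0.1, 0.5, 20)
    haps = (rng.random((50, 20)) < freqs).astype(np.uint8)
    # guard against monomorphic columns in this tiny draw
    haps[0] = 1
    haps[1] = 0
    return HaplotypePool(haps, [f"rs{i:02d}" for i in range(20)])


def random_dataset(rng, n_loci=8, n_cases=30, n_controls=30):
    """A random toy case-control dataset (no real genetic signal)."""
    genotypes = rng.integers(0, 3, size=(n_cases + n_controls, n_loci))
    status = np.array([1] * n_cases + [0] * n_controls)
    perm = rng.permutation(len(status))
    return CaseControlDataset(genotypes[perm].astype(np.int8),
                              status[perm].astype(np.int8),
                              [f"rs{i}" for i in range(n_loci)])


@pytest.fixture(scope="session")
def desk_pools():
    """Low- and high-relative-LD pools from the desk-scale simulation sweep.

    Shared across tests because the forward simulation is the most
    expensive fixture in the suite.
    """
    config = ExperimentConfig.desk_scale(seed=11)
    return config, simulate_and_select_pools(config)
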