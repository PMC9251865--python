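import numpy as np
import pytest

from poolscan import preprocess, synthetic_data as sd

POOLS = ["A", "B", "LB", "HV"]


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared across module tests."""
    cfg = sd.SimConfig(n_chrom=2, chrom_length=200_000, n_loci=4_000, seed=11)
    sites, truth = sd.simulate(cfg)
    return cfg, sites, truth


@pytest.fixture(scope="session")
def small_snps(small_sim):
    cfg, sites, _ = small_sim
    pc = preprocess.PoolConfig(pool_names=POOLS, seed=11)
    filtered = preprocess.subsample_depth(sites, pc)
    return preprocess.call_snps(filtered, pc)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
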