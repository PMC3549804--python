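import numpy as np
import pytest

from poolem import LocusData, ModelParams, PoolCounts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_locus():
    """Two pools of modest depth, K=4: small enough for brute-force oracles."""
    return LocusData((PoolCounts(8, 2), PoolCounts(9, 1)), 4, locus_id="toy")


@pytest.fixture
def rare_locus():
    """Typical rare-variant counts: G=2 pools, deep coverage."""
    return LocusData((PoolCounts(990, 10), PoolCounts(995, 5)), 100,
                     locus_id="rare")


def random_locus(rng, K_max=4, G_max=3, n_max=10):
    """Small random locus for property tests."""
    K = int(rng.integers(1, K_max + 1))
    G = int(rng.integers(1, G_max + 1))
    pools = []
    for _ in range(G):
        n = int(rng.integers(1, n_max + 1))
        n1 = int(rng.integers(0, n + 1))
        pools.append(PoolCounts(n - n1, n1))
    return LocusData(tuple(pools), K)
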