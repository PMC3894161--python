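import numpy as np
import pytest

import phylogp as pg


@pytest.fixture(scope="session")
def jtt():
    return pg.build_jtt_model()


@pytest.fixture(scope="session")
def quartet():
    """The canonical 4-taxon simulation tree (all branches 0.2)."""
    return pg.canonical_tree()


@pytest.fixture(scope="session")
def grid20():
    return pg.make_2d_grid(20, 20)


@pytest.fixture(scope="session")
def sim_config1(quartet, jtt, grid20):
    """One simulated 400-site replicate of the large-block configuration."""
    field = pg.block_rate_field(grid20, 10)
    rng = np.random.default_rng(42)
    aln = pg.simulate_alignment(quartet, jtt, field, rng)
    return aln, field


@pytest.fixture(scope="session")
def cache_config1(sim_config1, quartet, jtt):
    aln, _ = sim_config1
    return pg.build_cache(aln, quartet, jtt)
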