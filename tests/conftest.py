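import numpy as np
import pytest

from punctevo import (
    LineageTree,
    SimulationConfig,
    make_lineage,
    simulate_topology,
)

#: fixed seed for every stochastic test
SEED = 2025


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture()
def tree3():
    """((A:1,B:2):1,C:4); — the worked three-tip example."""
    return LineageTree.from_newick("((A:1,B:2):1,C:4);")


@pytest.fixture()
def tree8():
    return LineageTree.from_newick(
        "(((A:1,B:2):0.5,(C:1.5,D:0.7):1):0.8,"
        "((E:2,F:1):0.6,(G:0.9,H:1.1):1.2):0.4);"
    )


def random_trees(n_cases, tip_range=(4, 64), seed=SEED):
    """Yule trees of assorted sizes for property checks."""
    rng = np.random.default_rng(seed)
    return [
        simulate_topology(int(rng.integers(*tip_range)), 1.0, rng)
        for _ in range(n_cases)
    ]


@pytest.fixture(scope="session")
def punctuational_lineage():
    """A mid-size punctuational lineage reused across test modules."""
    return make_lineage(
        SimulationConfig(n_tips=200, target_pc=0.12, n_posterior=20, rng_seed=SEED)
    )


@pytest.fixture(scope="session")
def gradual_lineage():
    return make_lineage(
        SimulationConfig(n_tips=200, n_posterior=20, rng_seed=SEED + 1)
    )
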