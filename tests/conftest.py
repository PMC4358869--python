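import numpy as np
import pytest

from crossgs.config import SimConfig, TraitParams, smoke_sim_config
from crossgs.genome import GeneticMap
from crossgs.study import ReplicateBase, simulate_replicate_base


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trait_params():
    return TraitParams()


@pytest.fixture(scope="session")
def smoke_base() -> ReplicateBase:
    """One reduced-profile replicate base shared by read-only tests."""
    return simulate_replicate_base(smoke_sim_config(), TraitParams(),
                                   np.random.SeedSequence(777))


def uniform_map(n_loci: int, seed: int = 0) -> GeneticMap:
    """Evenly spaced loci spanning (0, 1) Morgans."""
    pos = (np.arange(n_loci) + 0.5) / n_loci
    return GeneticMap(positions=pos)
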