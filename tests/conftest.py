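import pytest

from exofrag.simulate import SimConfig, simulate_library
from exofrag.toyref import build_toy_reference

TOY_SEED = 11


@pytest.fixture(scope="session")
def toy():
    """Session-wide toy reference (genome + annotation)."""
    return build_toy_reference(TOY_SEED)


@pytest.fixture(scope="session")
def ann(toy):
    return toy.annotation


@pytest.fixture(scope="session")
def genome(toy):
    return toy.genome


@pytest.fixture(scope="session")
def wt_sim(toy):
    """One WT library with all library-prep biases neutral."""
    cfg = SimConfig(seed=5, n_reads=6000)
    return simulate_library(cfg, toy.annotation, toy.genome)


def gene(ann, gid):
    return ann[gid]
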