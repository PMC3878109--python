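import pytest

from hybase.design import TrioDesign, default_designs
from hybase.simulate import SimConfig, simulate_parents


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=200, seed=11)


@pytest.fixture(scope="session")
def small_parents(small_config):
    return simulate_parents(small_config)


@pytest.fixture(scope="session")
def gl_tq():
    return TrioDesign("GLxTQ", "GL", "TQ", reciprocal_id="TQxGL")


@pytest.fixture(scope="session")
def tq_gl():
    return TrioDesign("TQxGL", "TQ", "GL", reciprocal_id="GLxTQ")


@pytest.fixture(scope="session")
def six_designs():
    return default_designs(reciprocal=True)
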