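import numpy as np
import pytest

from sinepop.simulate import SimConfig, make_consensus


@pytest.fixture(scope="session")
def consensus():
    return make_consensus(1)


@pytest.fixture()
def cfg():
    return SimConfig(seed=11)


@pytest.fixture()
def rng(cfg):
    return cfg.rng()


@pytest.fixture()
def rng2():
    return np.random.default_rng(202)
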