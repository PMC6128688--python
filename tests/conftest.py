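import numpy as np
import pytest

from mechanopatch import build_preset
from mechanopatch.experiments import standard_poke_protocol, whole_cell_config


@pytest.fixture(scope="session")
def canonical_fast():
    return build_preset("canonical_fast")


@pytest.fixture(scope="session")
def mes_slow():
    return build_preset("mes_slow")


@pytest.fixture(scope="session")
def poke_protocol():
    return standard_poke_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def wc_config():
    return whole_cell_config(seed=7)
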