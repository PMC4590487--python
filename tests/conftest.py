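import numpy as np
import pytest

from mimicspec.vision import (WeberFractions, builtin_receptor_set,
                              flat_illuminant)


@pytest.fixture
def rng():
    return np.random.default_rng(20230117)


@pytest.fixture(scope="session")
def trichrom():
    return builtin_receptor_set("trichrom_skins")


@pytest.fixture(scope="session")
def tetra_uvs():
    return builtin_receptor_set("tetra_uvs")


@pytest.fixture(scope="session")
def weber3(trichrom):
    return trichrom.weber_fractions()


@pytest.fixture
def equal_weber3():
    return WeberFractions(np.array([0.05, 0.05, 0.05]),
                          ("SWS", "MWS", "LWS"))


@pytest.fixture(scope="session")
def illuminant():
    return flat_illuminant()
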