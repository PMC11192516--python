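import numpy as np
import pytest

from cortrack.montage import standard_64
from cortrack.paradigm import ParadigmSpec


@pytest.fixture(scope="session")
def spec() -> ParadigmSpec:
    return ParadigmSpec()


@pytest.fixture(scope="session")
def montage64():
    return standard_64()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
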