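import numpy as np
import pytest

from ramangrad import build_analyte_library, make_axis


@pytest.fixture(scope="session")
def axis():
    return make_axis()


@pytest.fixture(scope="session")
def library():
    return build_analyte_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
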