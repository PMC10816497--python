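import numpy as np
import pytest

from peakmotifs import make_fixture


@pytest.fixture(scope="session")
def mini_fixture():
    return make_fixture("mini", seed=11)


@pytest.fixture(scope="session")
def foxa2_fixture():
    return make_fixture("foxa2_like", seed=7)


@pytest.fixture(scope="session")
def null_fixture():
    return make_fixture("null", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
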