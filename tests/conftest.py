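import numpy as np
import pytest

from aquasoliton.synthetic import make_case


@pytest.fixture(scope="session")
def case_i():
    return make_case("I")


@pytest.fixture(scope="session")
def case_ii():
    return make_case("II")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
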