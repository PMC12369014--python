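import numpy as np
import pytest

from bacadhere.contact_mechanics import HYDRO_SOFTENED, UNSOFTENED


@pytest.fixture(scope="session")
def soft():
    return HYDRO_SOFTENED


@pytest.fixture(scope="session")
def unsoft():
    return UNSOFTENED


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
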