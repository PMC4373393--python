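import numpy as np
import pytest

from compcode import generate_digits
from compcode.preprocessing import Preprocessor


@pytest.fixture(scope="session")
def digits_small():
    """300 synthetic digits, enough for preprocessing/metric tests."""
    return generate_digits(300, seed=123)


@pytest.fixture(scope="session")
def preprocessed(digits_small):
    """Fitted preprocessor plus the on/off input vectors of the batch."""
    pp = Preprocessor().fit(digits_small)
    X = pp.transform(digits_small)
    return pp, X


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
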