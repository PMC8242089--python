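import warnings

import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
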