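import numpy as np
import pytest

from fbn.preprocess import standardize_columns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def std_small(rng):
    """Standardized 50×6 random time series."""
    return standardize_columns(rng.standard_normal((50, 6)))


@pytest.fixture
def std_medium(rng):
    """Standardized 40×8 random time series."""
    return standardize_columns(rng.standard_normal((40, 8)))
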