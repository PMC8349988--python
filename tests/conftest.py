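import numpy as np
import pytest

from texspec import FilterBankConfig, FixtureSpec, make_filter_bank, make_fixture


@pytest.fixture(scope="session")
def bank64():
    """Small bank: 64 px, 6 orientations, centers 2-32 cycles/image."""
    return make_filter_bank(FilterBankConfig(size=64, n_ori=6, n_freq=5, freq_min=2))


@pytest.fixture(scope="session")
def bandnoise64():
    """Band-passed noise whose spectrum lies inside bank64's coverage."""
    return make_fixture(FixtureSpec(kind="bandnoise", size=64, band=(4.0, 16.0), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
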