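import numpy as np
import pytest

from pamvlt import MCMCSettings, SurveyConfig


@pytest.fixture
def config():
    """A small survey grid: 5 bins of 100 m, ship at 5 m/s."""
    return SurveyConfig(
        truncation_perp_visual=1000.0,
        truncation_perp_acoustic=1000.0,
        max_forward_ahead=400.0,
        max_forward_behind=100.0,
        bin_width=100.0,
        ship_speed=5.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_mcmc():
    """Short chains for unit tests that only need a rough posterior."""
    return MCMCSettings(burn_in=600, iterations=1200, thin=3, chains=2)


@pytest.fixture
def single_chain_mcmc():
    """One short chain for parameter-recovery loops."""
    return MCMCSettings(burn_in=600, iterations=1000, thin=2, chains=1)
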