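"""Shared fixtures for the test suite."""

import numpy as np
import pytest
from hypothesis import settings

from tempopred.stimuli import draw_trials, get_condition

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg_4hz():
    return get_condition("4hz")


@pytest.fixture
def cfg_slow():
    return get_condition("1.2hz")


@pytest.fixture
def trials_4hz(cfg_4hz, rng):
    return draw_trials(cfg_4hz, 40, rng)
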