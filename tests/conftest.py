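import numpy as np
import pytest

from selfstim import AnalysisConfig, StimulusProtocol


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def protocol20():
    """Small 20-trial protocol for fast per-unit tests."""
    return StimulusProtocol.regular(n_trials=20)


@pytest.fixture
def protocol100():
    """The full 100-trial protocol."""
    return StimulusProtocol.regular(n_trials=100)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
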