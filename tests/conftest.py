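import numpy as np
import pytest
from hypothesis import settings

from mearetina import StimulusProtocol

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def short_protocol() -> StimulusProtocol:
    """One intensity, five repetitions — cheap trials for unit tests."""
    return StimulusProtocol(intensities_log=(7.67,), n_repetitions=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
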