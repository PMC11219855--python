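import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from doublepass import (
    DoublePassLookup,
    SequenceDesign,
    StimulusConfig,
    final_rise_template,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def stim_config() -> StimulusConfig:
    return StimulusConfig()


@pytest.fixture(scope="session")
def design() -> SequenceDesign:
    return SequenceDesign()


@pytest.fixture(scope="session")
def template() -> np.ndarray:
    return final_rise_template(6)


@pytest.fixture(scope="session")
def lookup() -> DoublePassLookup:
    """One Monte-Carlo lookup table shared by the whole suite."""
    return DoublePassLookup(seed=0)
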