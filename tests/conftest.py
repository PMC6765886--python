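import numpy as np
import pytest

from cigarsim import InitiationScenario, MortalityScenario


@pytest.fixture
def us_mortality() -> MortalityScenario:
    """The published nationwide mortality scenario (all defaults)."""
    return MortalityScenario()


@pytest.fixture
def us_initiation() -> InitiationScenario:
    """The published nationwide cohort-initiation scenario (all defaults)."""
    return InitiationScenario()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
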