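import numpy as np
import pytest

from arbisim import ScaledParameters, VariantGrid


@pytest.fixture
def params():
    return ScaledParameters()


@pytest.fixture
def grid101():
    """The standard constant-propensity study grid (phi 0..0.5 step 0.005)."""
    return VariantGrid.constant_propensity(np.arange(0, 0.5001, 0.005))


@pytest.fixture
def grid441():
    """The standard communication study grid (both axes 0..1 step 0.05)."""
    return VariantGrid.communication(np.arange(0, 1.0001, 0.05), np.arange(0, 1.0001, 0.05))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
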