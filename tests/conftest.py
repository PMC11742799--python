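import numpy as np
import pytest

from phasensor import CalibrationSet, phb_reference_model, phbv_reference_model


@pytest.fixture(scope="session")
def phb_model():
    """Reference PHB calibration: structure 7, a=8.2031, b=0.0556, c=3.1885."""
    return phb_reference_model()


@pytest.fixture(scope="session")
def phbv_model():
    """Reference PHBV calibration: structure 1, a=0.0404, b=1.4341."""
    return phbv_reference_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def linear_data():
    """Noisy points around y = 0.5 + 0.8 x."""
    rng = np.random.default_rng(7)
    x = np.linspace(0.5, 20, 12)
    y = 0.5 + 0.8 * x + rng.normal(0, 0.2, x.size)
    return CalibrationSet.from_arrays(x, y, label="linear")
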