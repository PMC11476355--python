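import numpy as np
import pytest

from steviaraman import build_library_calibrations


@pytest.fixture(scope="session")
def library_models():
    """Calibrations fitted on the noiseless twelve-compound synthetic library."""
    return build_library_calibrations(noise_sigma=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
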