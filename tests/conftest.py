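import numpy as np
import pytest

from biodosim.biodist import FLUORINE_18
from biodosim.resources import adult_phantom, moby_phantom
from biodosim.synth import SimConfig, simulate_study


@pytest.fixture(scope="session")
def f18():
    return FLUORINE_18


@pytest.fixture(scope="session")
def moby():
    return moby_phantom()


@pytest.fixture(scope="session")
def adult_f():
    return adult_phantom("F")


@pytest.fixture(scope="session")
def noiseless_study():
    """One zero-noise synthetic study: every record sits exactly on its truth curve."""
    cfg = SimConfig(noise_cv=0.0, seed=0)
    return cfg, simulate_study(cfg)


@pytest.fixture(scope="session")
def noisy_study():
    """Default study conditions: CV 15%, n=8 per sex per group."""
    cfg = SimConfig(seed=7)
    return cfg, simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
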