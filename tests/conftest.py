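import numpy as np
import pytest

from mpfmap.model import TwoPoolConstraints
from mpfmap.protocols import protocol_preset
from mpfmap.synthetic import PhantomSpec, make_phantom, simulate_acquisition


@pytest.fixture(scope="session")
def protocols():
    return protocol_preset()


@pytest.fixture(scope="session")
def constraints():
    return TwoPoolConstraints()


@pytest.fixture(scope="session")
def wm_gm_tissues():
    """Control-like subject tissue parameters for phantom construction."""
    return {
        "WM": {"f": 0.1304, "r1": 1.5, "pd": 0.7},
        "GM": {"f": 0.0644, "r1": 0.9, "pd": 0.85},
    }


@pytest.fixture(scope="session")
def phantom(wm_gm_tissues):
    return make_phantom(PhantomSpec(), wm_gm_tissues, rng_seed=7)


@pytest.fixture(scope="session")
def noiseless_images(phantom, protocols):
    return simulate_acquisition(phantom, protocols, 0.0, rng_seed=0)
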