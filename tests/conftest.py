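import warnings

import numpy as np
import pytest

from kbfmgmt import PhantomParams, make_phantom

# the KBF warns (by design) on empty intersections; keep test output clean
warnings.filterwarnings("ignore", message="KBF cross-intersection is empty")


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic small-preset phantom with a tumor."""
    return make_phantom(PhantomParams.small(), seed=11, label=0)


@pytest.fixture(scope="session")
def textured_phantom():
    """Positive (methylation) phantom: heterogeneous tumor texture."""
    return make_phantom(PhantomParams.small(), seed=13, label=1)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-preset phantom (96 voxels at 2 mm)."""
    return make_phantom(PhantomParams(), seed=5, label=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
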