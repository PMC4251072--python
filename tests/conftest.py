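import warnings

import numpy as np
import pytest

from retfdc.enhance import enhance
from retfdc.preprocess import preprocess_image
from retfdc.synth import FundusSynthParams, gen_synthetic_fundus


@pytest.fixture(scope="session")
def fundus_default():
    """One default synthetic fundus image with its annotation."""
    return gen_synthetic_fundus(FundusSynthParams(seed=7))


@pytest.fixture(scope="session")
def posterior_default(fundus_default):
    """Posterior vessel image of the default synthetic fundus (cached)."""
    img, od = fundus_default
    work = preprocess_image(img, od)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return enhance(work, seed=0)


@pytest.fixture(scope="session")
def small_params():
    """Small, fast phantom geometry (128 px frame, 32 px disc)."""
    return FundusSynthParams(image_size=128, od_diameter=32.0, width0=1.6, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
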