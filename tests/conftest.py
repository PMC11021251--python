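import numpy as np
import pytest

from neoseg import phantom


@pytest.fixture(scope="session")
def truth():
    """Default 64^3 phantom at 1 mm isotropic."""
    return phantom.make_phantom(phantom.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def truth_fine():
    """96^3 phantom at 0.63 mm isotropic — the production sampling regime."""
    return phantom.make_phantom(
        phantom.PhantomSpec(size=96, spacing=(0.63, 0.63, 0.63), seed=0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.2):
    m = rng.random(shape) < p
    return m
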