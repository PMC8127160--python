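import numpy as np
import pytest

from gpseg.phantom import PhantomSpec, sample_phantom_retry


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale phantom grid: coarse spacing, everything fits."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    img, lab, truth, _ = sample_phantom_retry(small_spec, seed=7)
    return img, lab, truth


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at the acquisition-matched 0.39 mm isotropic grid."""
    img, lab, truth, _ = sample_phantom_retry(PhantomSpec(), seed=11)
    return img, lab, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
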