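import numpy as np
import pytest

from xmpipe.phantom import PhantomSpec, render_phantom
from xmpipe.xray_io import NormImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return NormImage(rng.random((64, 64)))


@pytest.fixture(scope="session")
def phantom_pair():
    """Matched abnormal/normal phantom renders sharing a seed."""
    ab = render_phantom(PhantomSpec(size=128, abnormal=True, seed=7))
    nm = render_phantom(PhantomSpec(size=128, abnormal=False, seed=7))
    return ab, nm


@pytest.fixture(scope="session")
def phantom():
    return render_phantom(PhantomSpec(size=128, abnormal=True, seed=3))
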