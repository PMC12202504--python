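import numpy as np
import pytest

from pvatscope import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default straight-tube phantom: grid, aortic mask, ground truth."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def helical_phantom():
    spec = PhantomSpec(
        shape=(96, 96, 40),
        centerline="helical",
        helix_radius_mm=4.0,
        helix_pitch_mm=20.0,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
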