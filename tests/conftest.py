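import numpy as np
import pytest

from canalnet import PhantomSpec, render_phantom, straight_spec


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless straight tube centred in a 16x32x32 grid."""
    return render_phantom(straight_spec())


@pytest.fixture(scope="session")
def curved_phantom():
    """Noiseless curved tube (the default control polygon)."""
    return render_phantom(PhantomSpec(noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
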