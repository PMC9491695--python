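import numpy as np
import pytest

from hsistain.phantom import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """A representative noisy phantom strip shared by read-only tests."""
    return render_phantom(PhantomSpec.example((96, 144), noise_sd=0.02, seed=1))


@pytest.fixture(scope="session")
def noiseless_pair():
    return render_phantom(PhantomSpec.example((96, 144), noise_sd=0.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
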