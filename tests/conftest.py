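import numpy as np
import pytest

from eics.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A 6-slice 64x64 noise-free drifting phantom shared across tests."""
    return generate_phantom(
        PhantomSpec(n_slices=6, matrix_size=64, noise_sigma=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def small_slice(small_phantom):
    return small_phantom.data[0]
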