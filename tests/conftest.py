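import numpy as np
import pytest

from longimap.phantom import PhantomParams, generate_phantom_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def growth_phantom():
    """A misaligned, noisy phantom pair with a growing lesion (factor 1.6)."""
    return generate_phantom_pair(PhantomParams(growth_factor=1.6, seed=7))


@pytest.fixture(scope="session")
def clean_identity_phantom():
    """Identical timepoints: no growth, no misalignment, no noise."""
    params = PhantomParams(
        growth_factor=1.0, noise_sd=0.0,
        misalign_rotation_deg=(0.0, 0.0, 0.0),
        misalign_shift_px=(0.0, 0.0, 0.0), seed=3)
    return generate_phantom_pair(params)
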