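import numpy as np
import pytest

import fusdwi
from fusdwi.validation import fit_maps


@pytest.fixture(scope="session")
def lesioned_phantom():
    """Default-grid noiseless phantom with the default lesion effect."""
    return fusdwi.make_phantom(fusdwi.PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def lesioned_maps(lesioned_phantom):
    brain = lesioned_phantom.masks["brain"]
    return {
        "pre": fit_maps(lesioned_phantom.pre, brain),
        "post": fit_maps(lesioned_phantom.post, brain),
    }


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-grid noiseless phantom for fast unit checks."""
    return fusdwi.make_phantom(fusdwi.small_phantom_spec(seed=5))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-grid phantom at SNR 50 (s0=1000, sigma=20)."""
    return fusdwi.make_phantom(fusdwi.PhantomSpec(seed=7, noise_sigma=20.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
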