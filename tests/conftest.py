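import numpy as np
import pytest

from swimu import example_session_spec, generate_session


@pytest.fixture(scope="session")
def mixed_session():
    """One canonical noisy 8-lap mixed-style session with ground truth."""
    return generate_session(example_session_spec(seed=5))


@pytest.fixture(scope="session")
def clean_session():
    """The same layout with zero noise and no butterfly artifacts."""
    spec = example_session_spec(seed=5, noise_sd_deg=0.0, artifacts=False)
    spec.noise_sd_g = 0.0
    return generate_session(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
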