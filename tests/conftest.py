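import numpy as np
import pytest

from spinemark import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and occlusion-free spec for intensity calibration checks."""
    return PhantomSpec(noise_sd=0.0, occlusion_prob=0.0)


@pytest.fixture(scope="session")
def rigid_spec():
    """Fully deterministic geometry: no jitter, no tilt, no noise."""
    return PhantomSpec(
        noise_sd=0.0,
        occlusion_prob=0.0,
        spacing_jitter_sd=0.0,
        width_jitter_sd=0.0,
        height_jitter_sd=0.0,
        center_jitter_sd=0.0,
        tilt_sd=0.0,
    )


@pytest.fixture(scope="session")
def sample(default_spec):
    return generate_phantom(default_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
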