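import numpy as np
import pytest

from femhu import PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A fast ~220k-voxel phantom used throughout the unit tests."""
    defaults = dict(
        grid_shape=(72, 48, 64),
        head_radius_mm=10.0,
        neck_radius_mm=5.5,
        neck_length_mm=18.0,
        shaft_radius_mm=6.5,
        cortical_thickness_mm=2.0,
        lesser_trochanter_z_mm=20.0,
        noise_sd=0.0,
        random_seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free small phantom: (spec, volume, ground truth)."""
    spec = small_spec()
    volume, gt = generate_phantom(spec)
    return spec, volume, gt


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = small_spec(noise_sd=50.0, random_seed=11)
    volume, gt = generate_phantom(spec)
    return spec, volume, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
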