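import numpy as np
import pytest

from duofilm.phantom import PhantomParams
from duofilm.stack_io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A fast-but-realistic phantom: 30 µm deep at 0.5 µm voxels."""
    return PhantomParams(
        grid_shape=(60, 48, 48),
        n_filaments=2,
        filament_length=30.0,
        n_rods=60,
        seed=11,
    )


@pytest.fixture
def quiet_params(small_params):
    """Same geometry with all optical degradation switched off."""
    from dataclasses import replace

    return replace(
        small_params,
        psf_sigma=0.0,
        gauss_noise_sd=0.0,
        poisson_scale=0.0,
        attenuation_length=float("inf"),
    )


@pytest.fixture
def random_stack(rng):
    red = rng.integers(0, 256, size=(20, 24, 24), dtype=np.uint8)
    green = rng.integers(0, 256, size=(20, 24, 24), dtype=np.uint8)
    return ImageStack(red=red, green=green, voxel_spacing=(1.5, 0.8, 0.8))
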