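import numpy as np
import pytest

import lacunatex as lx


@pytest.fixture(scope="session")
def bernoulli32():
    """Seeded 32^3 i.i.d. volume at p = 0.7 (the random-texture reference)."""
    return lx.bernoulli_volume((32, 32, 32), 0.7, seed=123)


@pytest.fixture(scope="session")
def foam16():
    """Small seeded foam for oracle-equivalence checks."""
    spec = lx.SyntheticSpec(
        dims=(16, 16, 16),
        target_porosity=0.7,
        generator="foam",
        pore_radius_mean=3.0,
        pore_radius_sd=0.5,
        seed=7,
    )
    return lx.foam_volume(spec)


@pytest.fixture()
def noiseless_slice():
    """Two-valued grayscale slice plus its ground-truth pore mask."""
    vol = lx.bernoulli_volume((1, 64, 64), 0.7, seed=5)
    stack = lx.render_grayscale_stack(vol)
    return stack[0], vol.voxels[0]


@pytest.fixture()
def gradient_slice():
    """Noisy slice with an illumination ramp stronger than the contrast, so a
    single global threshold cannot be right on both sides of the image."""
    vol = lx.bernoulli_volume((1, 64, 64), 0.7, seed=7)
    stack = lx.render_grayscale_stack(
        vol, noise_sd=10.0, illumination_gradient=250.0, seed=8
    )
    return stack[0], vol.voxels[0]
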