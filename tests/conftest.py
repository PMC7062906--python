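import pytest

from marrowfat import PhantomConfig, generate_phantom, segment_stack

# Small, fast phantom for unit tests: 96-px grid at 0.08 cm/pixel keeps the
# default anatomy inside the field of view while segmenting in well under a
# second per slice.
FAST_KWARGS = dict(n_slices=6, grid_size=96, pixel_spacing=0.08, seed=42)


@pytest.fixture(scope="session")
def fast_config():
    return PhantomConfig(noise_sd=0.0, **FAST_KWARGS)


@pytest.fixture(scope="session")
def fast_phantom(fast_config):
    """Noise-free homogeneous phantom: (t1, fat, water, ground_truth)."""
    return generate_phantom(fast_config)


@pytest.fixture(scope="session")
def fast_seg(fast_phantom):
    t1, _, _, _ = fast_phantom
    return segment_stack(t1)


@pytest.fixture(scope="session")
def noisy_config():
    return PhantomConfig(noise_sd=10.0, **FAST_KWARGS)  # 5% of the fat signal


@pytest.fixture(scope="session")
def noisy_phantom(noisy_config):
    return generate_phantom(noisy_config)


@pytest.fixture(scope="session")
def speckled_config():
    return PhantomConfig(noise_sd=0.0, speckled=True, **FAST_KWARGS)


@pytest.fixture(scope="session")
def speckled_phantom(speckled_config):
    return generate_phantom(speckled_config)
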