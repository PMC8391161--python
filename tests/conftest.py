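import numpy as np
import pytest

from wormscope.synthgen import SynthConfig, generate_dish_image


def small_plate_config(seed=3, **overrides):
    """Desk-scale plate: 640 px square dish, easy (non-overlapping) worms."""
    defaults = dict(
        image_width=640,
        image_height=640,
        rim_width=20,
        n_worms=8,
        n_blobs=6,
        noise_sigma=0.0,
        allow_overlap=False,
        seed=seed,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def easy_plate():
    """One noise-free plate with 8 separated worms, 6 blobs, and its truth."""
    cfg = small_plate_config()
    image, gts = generate_dish_image(cfg)
    return cfg, image, gts


@pytest.fixture(scope="session")
def blank_plate():
    cfg = small_plate_config(n_worms=0, n_blobs=0)
    image, gts = generate_dish_image(cfg)
    return cfg, image, gts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
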