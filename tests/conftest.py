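import numpy as np
import pytest

from lenruler import SceneParams, SeedImage, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_params(seed=0, **overrides):
    """Compact scene parameters used throughout the suite (fast to render)."""
    defaults = dict(
        shape=(240, 320),
        n_seeds=3,
        radicle_length_range=(20.0, 60.0),
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)


@pytest.fixture
def scene():
    """A deterministic 3-seed scene with bezier radicles."""
    return generate_scene(small_params(seed=7))


@pytest.fixture
def straight_scene():
    """A deterministic scene with axis-aligned radicles (exact under weight 2)."""
    return generate_scene(small_params(seed=11, radicle_mode="straight_axis_aligned"))


def uniform_image(rgb, shape=(10, 10)):
    px = np.empty((*shape, 3), dtype=np.uint8)
    px[:] = np.array(rgb, dtype=np.uint8)
    return SeedImage(pixels=px, image_id="uniform")
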