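import numpy as np
import pytest

from neuromorph import GrayImage, get_preset
from neuromorph.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def criteria():
    return get_preset("synthetic")


@pytest.fixture(scope="session")
def junction_scene():
    """3 somata with exactly 2 neurites each: 6 ground-truth junctions."""
    return generate_scene(SceneSpec(n_somata=3, n_neurites_per_soma=(2, 2), n_debris=0, seed=105))


@pytest.fixture(scope="session")
def soma_scene():
    """Noise-free somata-only scene (two-valued image)."""
    return generate_scene(
        SceneSpec(n_somata=5, n_neurites_per_soma=(0, 0), n_debris=0, noise_sd=0.0, seed=103)
    )


def random_image(seed: int, shape=(16, 16), bit_depth=8) -> GrayImage:
    rng = np.random.default_rng(seed)
    return GrayImage(
        rng.integers(0, (1 << bit_depth), size=shape).astype(np.int64), bit_depth=bit_depth
    )
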