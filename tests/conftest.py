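import numpy as np
import pytest

import foascope as f


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free scene with a handful of well-separated cells, for speed."""
    return f.default_scene(seed=3, shape=(256, 256), n_live=5, n_dead=5,
                           noise_sigma=0.0)


@pytest.fixture(scope="session")
def default_scene_noisy():
    return f.default_scene(seed=11)
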