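import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene_samples():
    """A small clean 64x64 synthetic dataset shared across tests."""
    from leafdet.synthetic import SceneSpec, generate_dataset

    spec = SceneSpec(image_size=(64, 64), seed=7)
    samples, index = generate_dataset(spec, n_images=18)
    return samples, index
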