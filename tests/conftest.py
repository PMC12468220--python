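import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def easy_scene():
    """A clean three-nucleus scene with its exact ground truth."""
    from nucleoseg.synthetic import SceneSpec, generate_scene

    spec = SceneSpec(n_nuclei=3, noise_sigma=0.0, illumination_gradient=0.0, seed=7)
    rgb, mask = generate_scene(spec)
    return rgb, mask


def random_mask(rng, shape=(32, 32), p=0.4):
    return rng.random(shape) < p


@pytest.fixture
def random_masks(rng):
    return [random_mask(rng) for _ in range(10)]
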