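import numpy as np
import pytest

import mycospec as ms


@pytest.fixture(scope="session")
def mini_scene():
    """Small default scene: 4 grades, 48 x 48 px, 60 bands."""
    return ms.default_scene_config(n_bands=60, image_size=48)


@pytest.fixture(scope="session")
def mini_sample(mini_scene):
    return ms.generate_sample(mini_scene, 1, seed=1234)


@pytest.fixture(scope="session")
def mini_spectra(mini_scene):
    """Spectra of a small balanced dataset (8 per grade)."""
    return ms.spectra_from_samples(ms.iter_dataset(mini_scene, 8, 7), crop_n_bands=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
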