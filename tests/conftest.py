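import numpy as np
import pytest

from lamina import synthdata as sd
from lamina.images import image_array


@pytest.fixture(scope="session")
def scene_config():
    return sd.SceneConfig()


@pytest.fixture(scope="session")
def geometry(scene_config):
    return sd.SceneGeometry(scene_config)


@pytest.fixture(scope="session")
def reference_scene(scene_config):
    image, mask = sd.generate_reference_scene(scene_config)
    return image, mask


@pytest.fixture(scope="session")
def reference_image(reference_scene):
    return reference_scene[0]


@pytest.fixture(scope="session")
def clean_cohort(scene_config):
    """Zero-noise 20-gene cohort covering every truth class, plane C only."""
    truths = sd.make_default_truth(20, seed=0, noise_sd=0.0)
    records, table = sd.generate_gene_cohort(truths, scene_config, seed=1,
                                             planes=("C",))
    return truths, records, table


@pytest.fixture(scope="session")
def foreground(reference_image):
    return image_array(reference_image) > 0
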