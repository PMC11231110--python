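import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic_dataset(tmp_path_factory):
    """30 images (10/class) rendered at 224 px, loaded at 64 px for fast training."""
    from odfcanet.synth import SyntheticSpec, generate_dataset, load_image_folder

    root = tmp_path_factory.mktemp("synth30")
    generate_dataset(SyntheticSpec(per_class=10, seed=11), root)
    images, labels, classes = load_image_folder(root, size=64)
    return images, labels, classes
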