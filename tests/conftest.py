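import numpy as np
import pytest

from fecnet import nn as fnn
from fecnet.data import ImageFolderDataset, SyntheticSpec, generate_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(autouse=True)
def _seed_init():
    # deterministic parameter init for every test
    fnn.set_seed(1234)


@pytest.fixture(scope="session")
def tiny_folder(tmp_path_factory):
    """Small synthetic image tree: 4 classes x 5 images, 64 px."""
    root = tmp_path_factory.mktemp("tinyset")
    spec = SyntheticSpec(image_size=64, n_per_class=5, seed=7)
    inventory = generate_synthetic_dataset(spec, root)
    return root, inventory


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """Low-clutter synthetic set used by learnability/localization tests."""
    root = tmp_path_factory.mktemp("easyset")
    spec = SyntheticSpec(
        image_size=64,
        n_per_class=200,
        distractor_density=0.25,
        background_clutter_level=0.25,
        noise_sigma=0.01,
        seed=11,
    )
    inventory = generate_synthetic_dataset(spec, root)
    return ImageFolderDataset(inventory, image_size=64)


@pytest.fixture(scope="session")
def trained_tiny_model(easy_dataset):
    """Reduced-width four-stage network trained on the easy synthetic task.

    Shared by the Grad-CAM localization oracle and the learnability
    acceptance criterion (training once keeps the suite inside its budget).
    """
    from fecnet.backbone import build_network, scheme_config
    from fecnet.harness import train_model

    fnn.set_seed(1)
    net = build_network(
        scheme_config(14, base_width=8, stem_channels=8, stage_depths=(1, 1, 1, 1))
    )
    order = np.random.default_rng(1).permutation(len(easy_dataset))
    test_idx, train_idx = order[:160], order[160:]
    train_model(
        net, easy_dataset, train_idx,
        epochs=3, learning_rate=1e-3, batch_size=8, seed=1,
    )
    return net, test_idx
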