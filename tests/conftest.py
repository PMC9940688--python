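import numpy as np
import pytest

from camfuse import BackboneSpec, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_specs():
    """One small spec per backbone family, sized for 32x32 inputs."""
    return (
        BackboneSpec("cnn", input_size=(32, 32), embed_dim=4, depth=2,
                     num_classes=3, seed=0),
        BackboneSpec("vit", input_size=(32, 32), patch_size=8, embed_dim=8,
                     depth=1, num_classes=3, seed=1),
        BackboneSpec("swin", input_size=(32, 32), window_down=16, embed_dim=4,
                     depth=1, num_classes=3, seed=2),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 8 images with complementary view maps, in memory."""
    return generate_dataset(
        SyntheticSpec(n_classes=3, per_class=8, image_side=64, seed=7)
    )
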