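import numpy as np
import pytest

from lightmixer.blocks import BlockConfig
from lightmixer.datasets import (
    SyntheticClassRecipe,
    default_recipes,
    generate_synthetic_dataset,
)
from lightmixer.model import ModelConfig


@pytest.fixture
def tiny_model_cfg():
    """A narrow full architecture that forwards/backwards in milliseconds."""
    return ModelConfig(
        num_classes=4,
        channels=8,
        block_cfg=BlockConfig(channels=8, dropout_rate=0.0),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Ten-class synthetic set, 6 images per class at 32x32."""
    return generate_synthetic_dataset(
        recipes=default_recipes(), counts=[6] * 10, image_size=32, seed=7
    )


@pytest.fixture(scope="session")
def two_class_recipes():
    return [
        SyntheticClassRecipe(0, "spotty", (0.26, 0.32), (8, 12), (2.0, 4.0),
                             (60, 40, 20)),
        SyntheticClassRecipe(1, "clean", (0.28, 0.34), (0, 0), (0.0, 0.0),
                             (0, 0, 0)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
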