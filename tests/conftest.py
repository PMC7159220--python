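import numpy as np
import pytest

from grimace import nn
from grimace.synth import DatasetConfig, SceneParams, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small mixed-treatment study shared by read-only tests."""
    cfg = DatasetConfig(
        animals={"IN": 3, "KXN": 3, "C": 3, "untreated": 2},
        images_per_time=2,
        scene=SceneParams(image_size=(64, 64)),
    )
    return generate_dataset(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_tiny_cnn(seed: int = 0, size: int = 16, bias_free: bool = False,
                  nonneg_output: bool = False) -> nn.Sequential:
    """Small conv net for explanation/training tests."""
    rng = np.random.default_rng(seed)
    model = nn.Sequential([
        nn.Conv2D(1, 4, rng=rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Conv2D(4, 6, rng=rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Flatten(),
        nn.Dense(6 * (size // 4) ** 2, 8, rng=rng), nn.ReLU(),
        nn.Dense(8, 2, rng=rng), nn.Softmax(),
    ])
    if bias_free:
        for layer in model.layers:
            if hasattr(layer, "b"):
                layer.b[...] = 0.0
    if nonneg_output:
        final = model.layers[-2]
        final.W[...] = np.abs(final.W)
    return model
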