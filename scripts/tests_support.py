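"""Helpers for the reproduction script."""

import numpy as np

from grimace import nn


def make_bias_free_cnn(seed: int) -> nn.Sequential:
    """Random small CNN with zero biases and a non-negative output layer
    (so the predicted class always has a decomposable score)."""
    rng = np.random.default_rng(seed)
    model = nn.Sequential([
        nn.Conv2D(1, 4, rng=rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Conv2D(4, 6, rng=rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Flatten(),
        nn.Dense(6 * 16, 8, rng=rng), nn.ReLU(),
        nn.Dense(8, 2, rng=rng), nn.Softmax(),
    ])
    for layer in model.layers:
        if hasattr(layer, "b"):
            layer.b[...] = 0.0
    final = model.layers[-2]
    final.W[...] = np.abs(final.W)
    return model
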