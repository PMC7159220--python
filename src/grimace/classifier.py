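"""Binary facial-expression classifiers and their training regime.

Two classification paths:

(a) frozen backbone + head: features from a frozen convolutional base
    are classified by a single fully connected softmax layer (the
    transfer-learning path; the backbone is never updated);
(b) a small convolutional network trained from scratch: three 3x3
    convolutions with 32, 32 and 64 filters (each followed by a
    rectifier and 2x2 max-downsampling), two fully connected layers of
    128 units, and a 2-way softmax.

The training regime is fixed by :class:`TrainConfig`: Adam (learning
rate 0.001, beta1 0.9, beta2 0.999, epsilon 1e-07, no decay) minimizing
categorical cross-entropy, batch size 100, 50 epochs, a fresh random
permutation of the training set each epoch, inputs resized to 224x224
with bilinear interpolation and scaled to [0, 1].  No data augmentation
is applied by default.

Class order everywhere: index 0 = "effect", index 1 = "no_effect".
An image is called "effect" when that output activation is the larger
one; exact ties resolve to "effect" (for a welfare monitor the
conservative error is a false alarm).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn

__all__ = [
    "CLASSES",
    "TrainConfig",
    "Prediction",
    "preprocess",
    "preprocess_batch",
    "StubBackbone",
    "get_backbone",
    "BackboneUnavailableError",
    "extract_features",
    "build_head",
    "build_own_cnn",
    "train",
    "predict",
    "average_group_confidence",
    "save_model",
    "load_model",
]

CLASSES = ("effect", "no_effect")


def label_index(label: str) -> int:
    try:
        return CLASSES.index(label)
    except ValueError:
        raise ValueError(f"unknown class label {label!r}") from None


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, loss and schedule; defaults are the reference regime."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-07
    decay: float = 0.0
    loss: str = "categorical_crossentropy"
    batch_size: int = 100
    epochs: int = 50
    reshuffle_each_epoch: bool = True
    input_size: tuple[int, int] = (224, 224)
    resize_method: str = "bilinear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training hyperparameters")
        if self.resize_method != "bilinear":
            raise ValueError("only bilinear resizing is supported")

    def scaled(self, size: int, **overrides) -> "TrainConfig":
        """A scaled-down variant (smaller input); flagged as such in reports."""
        from dataclasses import replace
        return replace(self, input_size=(size, size), **overrides)


@dataclass(frozen=True)
class Prediction:
    """Two-class confidence vector plus the derived hard label."""

    confidence: tuple[float, float]   # (effect, no_effect), sums to 1
    hard_label: str

    def __post_init__(self) -> None:
        s = sum(self.confidence)
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"confidences sum to {s}, not 1")
        if self.hard_label not in CLASSES:
            raise ValueError(f"unknown hard label {self.hard_label!r}")

    @staticmethod
    def from_confidence(conf) -> "Prediction":
        conf = np.asarray(conf, dtype=float)
        conf = conf / conf.sum()
        # tie resolves to "effect" (index 0)
        label = CLASSES[0] if conf[0] >= conf[1] else CLASSES[1]
        return Prediction((float(conf[0]), float(conf[1])), label)


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(image: np.ndarray, config: TrainConfig) -> np.ndarray:
    """Resize to ``config.input_size`` (bilinear) and scale to [0, 1].

    Accepts (H, W) or (H, W, C) uint8/float arrays; returns float32
    (H', W', C).  A 224x224 input is passed through without resampling.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {arr.shape}")
    th, tw = config.input_size
    if arr.shape[:2] != (th, tw):
        channels = []
        for c in range(arr.shape[2]):
            pil = Image.fromarray(arr[:, :, c].astype(np.float32), mode="F")
            channels.append(np.asarray(
                pil.resize((tw, th), Image.Resampling.BILINEAR)))
        arr = np.stack(channels, axis=2)
    arr = arr.astype(np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def preprocess_batch(images, config: TrainConfig) -> np.ndarray:
    return np.stack([preprocess(im, config) for im in images])


# ---------------------------------------------------------------------------
# frozen-backbone path


class BackboneUnavailableError(RuntimeError):
    pass


class StubBackbone:
    """SYNTHETIC stand-in backbone: a frozen random-weight convolutional base.

    Serves the frozen-feature path wherever a pretrained base is
    unavailable: weights are random (seeded), never trained, and the
    feature map is the spatially pooled final convolutional
    representation projected to ``feature_dim``.  Random frozen
    convolutional features are a legitimate (if weak) representation;
    the point here is architectural, not ImageNet-level transfer.
    """

    name = "stub"

    def __init__(self, seed: int = 0, feature_dim: int = 256,
                 in_channels: int = 1) -> None:
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        self.in_channels = in_channels
        self._conv1 = nn.Conv2D(in_channels, 8, rng=rng)
        self._conv2 = nn.Conv2D(8, 16, rng=rng)
        # non-zero biases so a zero image still yields a bias-driven response
        self._conv1.b[...] = rng.normal(0.1, 0.05, 8).astype(np.float32)
        self._conv2.b[...] = rng.normal(0.1, 0.05, 16).astype(np.float32)
        self._proj = nn.Dense(16, feature_dim, rng=rng)
        self._pool = nn.MaxPool2D()
        self._relu = nn.ReLU()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in (self._conv1, self._conv2, self._proj)
                for p in layer.params]

    def transform(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W, C) [0, 1] batch -> (N, feature_dim) features."""
        x = np.asarray(images, dtype=np.float32)
        x = self._relu.forward(self._conv1.forward(x))
        x = self._pool.forward(x)
        x = self._relu.forward(self._conv2.forward(x))
        x = x.mean(axis=(1, 2))          # global average pool
        return self._proj.forward(x)


_BACKBONES = {"stub": StubBackbone}
_PRETRAINED_ONLY = ("resnet50", "inceptionv3")


def get_backbone(name: str, **kw):
    """Look up a feature-extraction backbone by name.

    ``resnet50`` and ``inceptionv3`` denote ImageNet-pretrained bases;
    their weights are not bundled with this package and must be supplied
    by an adapter, so requesting them raises with the available options.
    """
    if name in _BACKBONES:
        return _BACKBONES[name](**kw)
    if name in _PRETRAINED_ONLY:
        raise BackboneUnavailableError(
            f"backbone {name!r} requires pretrained weights that are not "
            f"bundled; available offline backbones: {sorted(_BACKBONES)}")
    raise ValueError(
        f"unknown backbone {name!r}; options: "
        f"{sorted(_BACKBONES) + list(_PRETRAINED_ONLY)}")


def extract_features(images: np.ndarray, backbone) -> np.ndarray:
    """Frozen, deterministic feature extraction; weights are never updated."""
    if isinstance(backbone, str):
        backbone = get_backbone(backbone)
    return backbone.transform(images)


# ---------------------------------------------------------------------------
# model construction


def build_head(feature_dim: int, seed: int = 0) -> nn.Sequential:
    """Single fully connected softmax layer: 2*feature_dim + 2 parameters."""
    rng = np.random.default_rng(seed)
    return nn.Sequential([nn.Dense(feature_dim, 2, rng=rng), nn.Softmax()])


def build_own_cnn(input_size: tuple[int, int] = (224, 224),
                  in_channels: int = 1, seed: int = 0) -> nn.Sequential:
    """The from-scratch architecture: conv32-conv32-conv64, FC128-FC128-2.

    Each convolution is 3x3 (stride 1, zero padding) followed by a
    rectifier and 2x2 max-downsampling; the input sides must therefore
    be divisible by 8 and at least 8.
    """
    h, w = input_size
    if h % 8 or w % 8 or h < 8 or w < 8:
        raise ValueError(
            f"input size {h}x{w} incompatible with three 2x2 downsampling "
            "stages; sides must be multiples of 8 and >= 8")
    rng = np.random.default_rng(seed)
    flat = (h // 8) * (w // 8) * 64
    return nn.Sequential([
        nn.Conv2D(in_channels, 32, rng=rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Conv2D(32, 32, rng=rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Conv2D(32, 64, rng=rng), nn.ReLU(), nn.MaxPool2D(),
        nn.Flatten(),
        nn.Dense(flat, 128, rng=rng), nn.ReLU(),
        nn.Dense(128, 128, rng=rng), nn.ReLU(),
        nn.Dense(128, 2, rng=rng), nn.Softmax(),
    ])


# ---------------------------------------------------------------------------
# training and prediction


def train(model: nn.Sequential, x: np.ndarray, labels,
          config: TrainConfig | None = None, *, augment=None) -> list[float]:
    """Train ``model`` on preprocessed inputs; returns the loss trace.

    ``labels`` may be class strings or indices.  Exactly
    ``config.epochs`` passes are made; each epoch visits every example
    once in a fresh seeded permutation.  ``augment`` is an optional
    per-batch hook ``augment(batch, rng) -> batch``; the reference
    regime applies no augmentation.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        labels = np.array([label_index(l) for l in labels])
    if len(x) == 0:
        raise ValueError("empty training set")
    return nn.fit(
        model, np.asarray(x, dtype=np.float32), labels,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, beta1=config.beta1,
        beta2=config.beta2, epsilon=config.epsilon, decay=config.decay,
        seed=config.seed, augment=augment)


def predict(model: nn.Sequential, x: np.ndarray,
            batch_size: int = 256) -> list[Prediction]:
    proba = model.predict_proba(np.asarray(x, dtype=np.float32), batch_size)
    return [Prediction.from_confidence(p) for p in proba]


def average_group_confidence(
    predictions: list[Prediction],
    records: pd.DataFrame,
    group_keys: tuple[str, ...] = ("animal_id", "time_label"),
) -> pd.DataFrame:
    """Classify (animal, time) groups by their mean confidence vector.

    Every prediction must join to a record (same order and length); the
    hard label of a group follows the averaged confidence, not the
    majority vote of its members.  Groups of size one pass through
    unchanged.
    """
    if len(predictions) != len(records):
        raise ValueError(
            f"{len(predictions)} predictions for {len(records)} records; "
            "every prediction must join to exactly one record")
    df = records.reset_index(drop=True).copy()
    df["conf_effect"] = [p.confidence[0] for p in predictions]
    df["conf_no_effect"] = [p.confidence[1] for p in predictions]
    rows = []
    for keys, grp in df.groupby(list(group_keys), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        conf = np.array([grp["conf_effect"].mean(), grp["conf_no_effect"].mean()])
        pred = Prediction.from_confidence(conf)
        row = dict(zip(group_keys, keys))
        row.update(conf_effect=pred.confidence[0],
                   conf_no_effect=pred.confidence[1],
                   hard_label=pred.hard_label, n_images=len(grp))
        if "binary_label" in grp.columns:
            row["binary_label"] = grp["binary_label"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence: weights as npz + JSON sidecar


def save_model(model: nn.Sequential, outdir, *, arch: str,
               config: TrainConfig | None = None, seed: int | None = None,
               extra: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(outdir / "weights.npz",
             **{f"p{i}": w for i, w in enumerate(weights)})
    spec = {
        "arch": arch,
        "layers": [type(l).__name__ for l in model.layers],
        "shapes": [list(w.shape) for w in weights],
        "seed": seed,
        "config": asdict(config) if config else None,
    }
    if extra:
        spec.update(extra)
    (outdir / "model.json").write_text(json.dumps(spec, indent=2))


def load_model(indir, builder=None) -> nn.Sequential:
    """Rebuild a saved model; ``builder`` overrides the default registry."""
    indir = Path(indir)
    spec = json.loads((indir / "model.json").read_text())
    if builder is not None:
        model = builder()
    elif spec["arch"] == "own":
        size = spec.get("config", {}).get("input_size", (224, 224)) if spec.get("config") else (224, 224)
        model = build_own_cnn(tuple(size))
    elif spec["arch"] == "head":
        model = build_head(spec["shapes"][0][0])
    else:
        raise ValueError(f"unknown architecture {spec['arch']!r}")
    with np.load(indir / "weights.npz") as z:
        model.set_weights([z[f"p{i}"] for i in range(len(z.files))])
    return model
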