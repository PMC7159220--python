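"""Deep Taylor decomposition: pixel-wise relevance for one prediction.

The chosen output neuron's pre-softmax activation is propagated
backwards through the network and redistributed layer by layer until it
is decomposed into per-pixel contributions, rendered as red heatmaps.

Propagation rules (the standard deep-Taylor prescription):

* dense / convolution hidden layers: positive-share (z+) rule — each
  input neuron receives relevance proportional to its positive
  contribution (activation x positive weight part) to each output it
  feeds, normalized per output neuron; biases are ignored, which makes
  the rule exactly conserving on bias-free networks;
* the input layer: box (z^B) rule, which respects the declared input
  value range (images live in [0, 1] after preprocessing);
* max-downsampling: relevance is routed entirely to the winning
  location; rectifiers and reshapes pass relevance through unchanged.

Properties (tested): per-layer relevance sums equal the explained score
on bias-free networks; all relevances are non-negative for non-negative
activations under these rules; denominators below 1e-12 drop that
output's relevance with a logged conservation warning rather than
dividing by zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import CLASSES, label_index
from .nn import Conv2D, Dense, Flatten, Layer, MaxPool2D, ReLU, Sequential, Softmax

logger = logging.getLogger(__name__)

__all__ = [
    "RelevanceMap",
    "LayerActivation",
    "forward_collect",
    "replay",
    "dtd_relevance",
    "render_heatmap",
    "conservation_report",
]

_SUPPORTED = (Dense, Conv2D, MaxPool2D, ReLU, Flatten, Softmax)
_EPS = 1e-12


@dataclass(frozen=True)
class LayerActivation:
    """One layer's exact input and output from a collected forward pass."""

    name: str
    layer: Layer
    input: np.ndarray
    output: np.ndarray


@dataclass
class RelevanceMap:
    """Per-pixel relevance explaining one prediction."""

    relevance: np.ndarray            # (H, W), channel-summed
    explained_class: str
    explained_score: float
    layer_sums: list[float] = field(default_factory=list)
    dropped: float = 0.0             # relevance lost to division guards


def forward_collect(model: Sequential, x: np.ndarray) -> list[LayerActivation]:
    """Run one input through the model, recording every layer's input/output.

    ``x`` is a single image (H, W, C) or feature vector (D,); a leading
    batch axis of one is added.  Raises on unsupported layer types.
    """
    for layer in model.layers:
        if not isinstance(layer, _SUPPORTED):
            raise TypeError(
                f"unsupported layer type {type(layer).__name__}; supported: "
                f"{[c.__name__ for c in _SUPPORTED]}")
    x = np.asarray(x, dtype=np.float32)
    if x.ndim in (1, 3):
        x = x[None]
    records = []
    for layer in model.layers:
        out = layer.forward(x)
        records.append(LayerActivation(type(layer).__name__, layer, x, out))
        x = out
    return records


def replay(records: list[LayerActivation]) -> np.ndarray:
    """Re-run each recorded layer on its recorded input; returns the final
    output (bitwise equal to the collected pass)."""
    out = None
    for rec in records:
        out = rec.layer.forward(rec.input)
    return out


def _guarded_ratio(r: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, float]:
    """r / z with tiny denominators dropped; returns (ratio, dropped sum)."""
    bad = np.abs(z) < _EPS
    dropped = float(np.abs(r[bad]).sum())
    if dropped > 0:
        logger.warning(
            "relevance conservation: dropped %.3g relevance at %d neurons "
            "with near-zero denominators", dropped, int(bad.sum()))
    s = np.zeros_like(r)
    np.divide(r, z, out=s, where=~bad)
    return s, dropped


def _dense_zplus(layer: Dense, x: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, float]:
    x = x.astype(np.float64)
    wp = np.maximum(layer.W.astype(np.float64), 0.0)
    z = x @ wp
    s, dropped = _guarded_ratio(r, z)
    return x * (s @ wp.T), dropped


def _dense_zb(layer: Dense, x: np.ndarray, r: np.ndarray,
              lo: float, hi: float) -> tuple[np.ndarray, float]:
    x = x.astype(np.float64)
    w = layer.W.astype(np.float64)
    wp, wn = np.maximum(w, 0.0), np.minimum(w, 0.0)
    z = x @ w - lo * wp.sum(axis=0) - hi * wn.sum(axis=0)
    s, dropped = _guarded_ratio(r, z)
    return x * (s @ w.T) - lo * (s @ wp.T) - hi * (s @ wn.T), dropped


def _conv_cols(layer: Conv2D, x: np.ndarray) -> np.ndarray:
    return layer.patches(x).astype(np.float64)


def _pool_route(layer: MaxPool2D, r: np.ndarray) -> np.ndarray:
    """Winner-take-all relevance routing (float64 variant of the pooling
    backward pass, reusing the winner masks of the collected forward)."""
    shape, m_ab, m_cd, m_tb = layer._cache
    out = np.zeros(shape, dtype=np.float64)
    out[:, 0::2, 0::2, :] = np.where(m_tb & m_ab, r, 0.0)
    out[:, 0::2, 1::2, :] = np.where(m_tb & ~m_ab, r, 0.0)
    out[:, 1::2, 0::2, :] = np.where(~m_tb & m_cd, r, 0.0)
    out[:, 1::2, 1::2, :] = np.where(~m_tb & ~m_cd, r, 0.0)
    return out


def _conv_scatter(layer: Conv2D, rcols: np.ndarray,
                  in_shape: tuple[int, ...]) -> np.ndarray:
    """col2im: accumulate per-patch relevance back onto input pixels."""
    n, h, w, c = in_shape
    k = layer.ksize
    p = k // 2
    rc = rcols.reshape(n, h, w, k, k, c)
    rp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=rcols.dtype)
    for i in range(k):
        for j in range(k):
            rp[:, i:i + h, j:j + w, :] += rc[:, :, :, i, j, :]
    return rp[:, p:p + h, p:p + w, :]


def _conv_zplus(layer: Conv2D, x: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, float]:
    cols = _conv_cols(layer, x)
    wp = np.maximum(layer.W.astype(np.float64), 0.0)
    z = cols @ wp
    rf = r.reshape(z.shape)
    s, dropped = _guarded_ratio(rf, z)
    rcols = cols * (s @ wp.T)
    return _conv_scatter(layer, rcols, x.shape), dropped


def _conv_zb(layer: Conv2D, x: np.ndarray, r: np.ndarray,
             lo: float, hi: float) -> tuple[np.ndarray, float]:
    cols = _conv_cols(layer, x)
    # zero padding is not part of the input domain: the box-rule range
    # terms must only cover valid pixels, or relevance leaks into padding
    mask = _conv_cols(layer, np.ones_like(x))
    w = layer.W.astype(np.float64)
    wp, wn = np.maximum(w, 0.0), np.minimum(w, 0.0)
    z = cols @ w - lo * (mask @ wp) - hi * (mask @ wn)
    rf = r.reshape(z.shape)
    s, dropped = _guarded_ratio(rf, z)
    rcols = cols * (s @ w.T) - (lo * mask) * (s @ wp.T) - (hi * mask) * (s @ wn.T)
    return _conv_scatter(layer, rcols, x.shape), dropped


def dtd_relevance(
    model: Sequential,
    x: np.ndarray,
    target_class: str | None = None,
    *,
    input_range: tuple[float, float] = (0.0, 1.0),
    input_rule: str = "zB",
) -> RelevanceMap:
    """Decompose one prediction into per-pixel relevances.

    ``target_class`` defaults to the predicted class.  The explained
    quantity is the target neuron's pre-softmax activation, which must
    be non-negative.  ``input_rule`` selects the rule for the first
    layer: "zB" (box rule over ``input_range``, for image inputs) or
    "z+" (for non-negative feature inputs).
    """
    records = forward_collect(model, x)
    if not isinstance(records[-1].layer, Softmax):
        raise ValueError("model must end in a softmax layer")
    logits = records[-1].input[0]
    if target_class is None:
        target = int(np.argmax(logits))
    else:
        target = label_index(target_class) if isinstance(target_class, str) else int(target_class)
    score = float(logits[target])
    if score < 0:
        raise ValueError(
            f"pre-softmax activation of class {CLASSES[target]!r} is "
            f"{score:.4g} < 0 and cannot be decomposed; explain the other "
            "class or a different input")

    r = np.zeros(records[-1].input.shape, dtype=np.float64)
    r[0, target] = score
    lo, hi = input_range
    dropped_total = 0.0
    sums = [float(r.sum())]
    feature_records = records[:-1]
    for i in range(len(feature_records) - 1, -1, -1):
        rec = feature_records[i]
        layer, xin = rec.layer, rec.input
        is_input_layer = i == 0
        if isinstance(layer, ReLU):
            pass  # relevance passes through the rectifier unchanged
        elif isinstance(layer, Flatten):
            r = r.reshape(xin.shape)
        elif isinstance(layer, MaxPool2D):
            r = _pool_route(layer, r)  # winner-take-all routing
        elif isinstance(layer, Dense):
            if is_input_layer and input_rule == "zB":
                r, d = _dense_zb(layer, xin, r, lo, hi)
            else:
                r, d = _dense_zplus(layer, xin, r)
            dropped_total += d
        elif isinstance(layer, Conv2D):
            if is_input_layer and input_rule == "zB":
                r, d = _conv_zb(layer, xin, r, lo, hi)
            else:
                r, d = _conv_zplus(layer, xin, r)
            dropped_total += d
        sums.append(float(r.sum()))
    sums.reverse()
    rel = r[0]
    if rel.ndim == 3:
        rel = rel.sum(axis=2)
    return RelevanceMap(
        relevance=rel,
        explained_class=CLASSES[target],
        explained_score=score,
        layer_sums=sums,
        dropped=dropped_total,
    )


# ---------------------------------------------------------------------------
# rendering


def render_heatmap(
    relevance_map: RelevanceMap | np.ndarray,
    original_image: np.ndarray,
    mode: str = "side_by_side",
    alpha: float = 0.6,
) -> np.ndarray:
    """Render a relevance heatmap as a uint8 RGB image.

    Relevance is normalized to [0, 1] by its maximum (an all-zero map
    stays zero).  ``mode``: "heat" (red-scale map alone), "overlay"
    (alpha blend onto the image), or "side_by_side" (original | overlay
    | heat, three panels wide).
    """
    rel = relevance_map.relevance if isinstance(relevance_map, RelevanceMap) else np.asarray(relevance_map)
    img = np.asarray(original_image)
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[:, :, 0]
    if rel.shape != img.shape[:2]:
        raise ValueError(
            f"relevance shape {rel.shape} incompatible with image {img.shape}")
    mx = rel.max()
    norm = rel / mx if mx > 0 else np.zeros_like(rel)
    norm = np.clip(norm, 0.0, 1.0)

    heat = np.zeros((*rel.shape, 3), dtype=np.float32)
    heat[:, :, 0] = norm * 255.0           # red-scale: black -> red

    if img.ndim == 2:
        base = np.repeat(img[:, :, None], 3, axis=2).astype(np.float32)
    else:
        base = img[:, :, :3].astype(np.float32)
    if base.max() <= 1.0:
        base = base * 255.0
    a = alpha * norm[:, :, None]
    red = np.zeros_like(base)
    red[:, :, 0] = 255.0
    overlay = base * (1.0 - a) + red * a

    if mode == "heat":
        out = heat
    elif mode == "overlay":
        out = overlay
    elif mode == "side_by_side":
        out = np.concatenate([base, overlay, heat], axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.clip(out, 0, 255).astype(np.uint8)


def conservation_report(model: Sequential, inputs: np.ndarray,
                        **dtd_kw) -> tuple[pd.DataFrame, float]:
    """Per-layer relevance sums for each input, plus the maximum relative
    deviation from the explained score.

    On bias-free networks the deviation is numerically zero; biases
    absorb relevance, so for biased networks the deviation is reported,
    not asserted.
    """
    inputs = np.asarray(inputs)
    if len(inputs) == 0:
        raise ValueError("empty input batch")
    rows = []
    max_dev = 0.0
    for i, x in enumerate(inputs):
        rm = dtd_relevance(model, x, **dtd_kw)
        denom = abs(rm.explained_score) if rm.explained_score else 1.0
        devs = [abs(s - rm.explained_score) / denom for s in rm.layer_sums]
        max_dev = max(max_dev, max(devs))
        for li, s in enumerate(rm.layer_sums):
            rows.append({"input": i, "boundary": li, "relevance_sum": s,
                         "explained_score": rm.explained_score,
                         "relative_deviation": devs[li]})
    return pd.DataFrame(rows), max_dev
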