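"""Two-stage mouse-face localization.

Stage 1 is a whole-face detector based on boosted cascades of simple
(Haar-like) rectangle features evaluated on a multi-scale sliding
window.  When it yields no detection, stage 2 falls back to separate
eye and ear part detectors whose grouped detections must pass
geometric plausibility heuristics of a typical face — most importantly,
the ears must be above the eyes.  Accepted hypotheses are cropped with
a configurable margin.

The boosting machinery is deliberately small-scale: decision stumps
over a random sample of Haar-like features (geometry enumerated by
scikit-image, stumps fitted by scikit-learn gradient boosting), trained
on synthetic positive/negative crops.  Externally trained models
serialized to the package's JSON format are accepted interchangeably.

Coordinate convention everywhere: 0-based, half-open boxes
[x0, x1) x [y0, y1), y increasing downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import haar_like_feature_coord
from skimage.transform import resize
from sklearn.ensemble import GradientBoostingClassifier


__all__ = [
    "BoundingBox",
    "FaceHypothesis",
    "GeometricRules",
    "HaarStumpDetector",
    "iou",
    "train_detector",
    "group_detections",
    "detect_whole_face",
    "detect_parts",
    "geometric_filter",
    "select_part_group",
    "two_stage_detect",
    "crop_to_hypothesis",
    "detection_report",
    "laplacian_energy",
]


@dataclass(frozen=True, order=True)
class BoundingBox:
    x0: int
    y0: int
    x1: int
    y1: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.x0 >= self.x1 or self.y0 >= self.y1:
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def clipped(self, h: int, w: int) -> "BoundingBox":
        return BoundingBox(max(self.x0, 0), max(self.y0, 0),
                           min(self.x1, w), min(self.y1, h), self.score)


def iou(a, b) -> float:
    """Intersection over union of two half-open boxes (tuples or BoundingBox)."""
    ax0, ay0, ax1, ay1 = (a.x0, a.y0, a.x1, a.y1) if isinstance(a, BoundingBox) else a[:4]
    bx0, by0, bx1, by1 = (b.x0, b.y0, b.x1, b.y1) if isinstance(b, BoundingBox) else b[:4]
    ix = max(0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union else 0.0


@dataclass
class FaceHypothesis:
    """Candidate face localization from either detection stage."""

    face_box: BoundingBox | None
    eye_boxes: list[BoundingBox] = field(default_factory=list)
    ear_boxes: list[BoundingBox] = field(default_factory=list)
    source: str = "whole_face"            # or "parts_fallback"
    accepted: bool = False
    rejection_reason: str | None = None


# ---------------------------------------------------------------------------
# Haar features and boosted stumps

_FEATURE_TYPES = ("type-2-x", "type-2-y", "type-3-x", "type-3-y", "type-4")

# per-type rectangle signs matching skimage's haar_like_feature values
_TYPE_SIGNS = {
    "type-2-x": (-1, 1),
    "type-2-y": (-1, 1),
    "type-3-x": (-1, 1, -1),
    "type-3-y": (-1, 1, -1),
    "type-4": (-1, 1, -1, 1),
}


def _pad_integral(img: np.ndarray) -> np.ndarray:
    """Integral image with a leading zero row/column, so the sum of the
    half-open rectangle [r0, r1) x [c0, c1) is
    ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]."""
    ii = np.cumsum(np.cumsum(np.asarray(img, dtype=np.float64), axis=0), axis=1)
    return np.pad(ii, ((1, 0), (1, 0)))


@dataclass(frozen=True)
class HaarFeature:
    """Signed rectangles in half-open window coordinates."""

    feature_type: str
    rects: tuple[tuple[int, int, int, int, int], ...]   # (sign, r0, c0, r1, c1)

    @staticmethod
    def from_skimage(feature_type: str, coord) -> "HaarFeature":
        signs = _TYPE_SIGNS[feature_type]
        rects = tuple(
            (s, r0, c0, r1 + 1, c1 + 1)         # inclusive -> half-open
            for s, ((r0, c0), (r1, c1)) in zip(signs, coord))
        return HaarFeature(feature_type, rects)


def enumerate_features(window: int, rng: np.random.Generator,
                       n_features: int) -> list[HaarFeature]:
    """Random sample from the full Haar feature set of a square window."""
    feats: list[HaarFeature] = []
    for ft in _FEATURE_TYPES:
        coords, types = haar_like_feature_coord(window, window, ft)
        feats.extend(HaarFeature.from_skimage(ft, c) for c in coords)
    if n_features >= len(feats):
        return feats
    idx = rng.choice(len(feats), size=n_features, replace=False)
    return [feats[i] for i in sorted(idx)]


def _eval_features_windows(ii2: np.ndarray, features: list[HaarFeature],
                           window: int, stride: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate every feature on every sliding-window origin.

    Returns (X, ys, xs): X has shape (n_windows, n_features); ys/xs are
    the window origins (top-left corner, image coordinates).
    """
    h, w = ii2.shape[0] - 1, ii2.shape[1] - 1
    ys = np.arange(0, h - window + 1, stride)
    xs = np.arange(0, w - window + 1, stride)
    if len(ys) == 0 or len(xs) == 0:
        return np.empty((0, len(features))), ys, xs
    x = np.zeros((len(ys), len(xs), len(features)))
    for fi, feat in enumerate(features):
        acc = np.zeros((len(ys), len(xs)))
        for s, r0, c0, r1, c1 in feat.rects:
            acc += s * (ii2[np.ix_(ys + r1, xs + c1)]
                        - ii2[np.ix_(ys + r0, xs + c1)]
                        - ii2[np.ix_(ys + r1, xs + c0)]
                        + ii2[np.ix_(ys + r0, xs + c0)])
        x[:, :, fi] = acc
    return x.reshape(len(ys) * len(xs), len(features)), ys, xs


def extract_crop_features(crops: np.ndarray, features: list[HaarFeature],
                          window: int) -> np.ndarray:
    """Feature matrix for pre-sized (n, window, window) crops."""
    out = np.zeros((len(crops), len(features)))
    for i, crop in enumerate(crops):
        ii2 = _pad_integral(crop)
        x, _, _ = _eval_features_windows(ii2, features, window, stride=window)
        out[i] = x[0]
    return out


@dataclass
class HaarStumpDetector:
    """Boosted decision stumps over Haar-like features, with a score threshold.

    ``stumps`` rows are (feature_index, split_threshold, left_value,
    right_value); the window score is the additive-boosting raw score
    (log-odds scale): ``bias + learning_rate * sum(stump values)``.
    Higher means more face-like; ``threshold`` is the acceptance cut.
    """

    window: int
    features: list[HaarFeature]
    stumps: list[tuple[int, float, float, float]]
    bias: float = 0.0
    learning_rate: float = 1.0
    threshold: float = 0.0
    name: str = "detector"

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        total = np.full(len(x), self.bias)
        for fi, thr, left, right in self.stumps:
            total += self.learning_rate * np.where(x[:, fi] <= thr, left, right)
        return total

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "window": self.window,
            "threshold": self.threshold,
            "bias": self.bias,
            "learning_rate": self.learning_rate,
            "features": [
                {"type": f.feature_type, "rects": [list(r) for r in f.rects]}
                for f in self.features],
            "stumps": [list(s) for s in self.stumps],
        })

    @staticmethod
    def from_json(text: str) -> "HaarStumpDetector":
        d = json.loads(text)
        return HaarStumpDetector(
            window=d["window"],
            features=[HaarFeature(f["type"], tuple(tuple(r) for r in f["rects"]))
                      for f in d["features"]],
            stumps=[tuple(s) for s in d["stumps"]],
            bias=d.get("bias", 0.0),
            learning_rate=d.get("learning_rate", 1.0),
            threshold=d["threshold"],
            name=d.get("name", "detector"),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @staticmethod
    def load(path) -> "HaarStumpDetector":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"cascade model file not found: {path}")
        return HaarStumpDetector.from_json(path.read_text())


def _crop_resize(image: np.ndarray, box, window: int) -> np.ndarray:
    x0, y0, x1, y1 = box[:4]
    crop = np.asarray(image, dtype=float)[max(y0, 0):y1, max(x0, 0):x1]
    if crop.size == 0:
        raise ValueError(f"empty crop for box {box}")
    return resize(crop, (window, window), anti_aliasing=True)


def train_detector(
    pos_crops,
    neg_crops,
    *,
    window: int = 24,
    n_features: int = 250,
    n_estimators: int = 50,
    seed: int = 0,
    name: str = "detector",
) -> HaarStumpDetector:
    """Train a boosted-stump detector from positive/negative crops.

    Crops may be any size; they are resized to the square training
    window.  The default decision threshold is the midpoint between the
    median positive and median negative training scores.
    """
    rng = np.random.default_rng(seed)
    features = enumerate_features(window, rng, n_features)
    crops = [resize(np.asarray(c, dtype=float), (window, window), anti_aliasing=True)
             if c.shape != (window, window) else np.asarray(c, dtype=float)
             for c in (*pos_crops, *neg_crops)]
    x = extract_crop_features(np.stack(crops), features, window)
    y = np.r_[np.ones(len(pos_crops), dtype=int), np.zeros(len(neg_crops), dtype=int)]
    lr = 0.3
    booster = GradientBoostingClassifier(
        n_estimators=n_estimators, max_depth=1, learning_rate=lr,
        subsample=0.8, random_state=int(rng.integers(2 ** 31)))
    booster.fit(x, y)
    bias = float(np.ravel(booster.init_.predict_proba(x[:1]))[1])
    bias = float(np.log(bias / (1.0 - bias)))   # prior log-odds
    stumps = []
    for est in booster.estimators_[:, 0]:
        tree = est.tree_
        stumps.append((int(tree.feature[0]), float(tree.threshold[0]),
                       float(tree.value[1].ravel()[0]),
                       float(tree.value[2].ravel()[0])))
    det = HaarStumpDetector(window=window, features=features, stumps=stumps,
                            bias=bias, learning_rate=lr, name=name)
    scores = det.decision_scores(x)
    # sensitivity-oriented operating point: nearly all aligned positives
    # must pass (a sliding window maximizes over thousands of windows,
    # so easy negatives are irrelevant to the cut)
    det.threshold = float(np.quantile(scores[y == 1], 0.05))
    return det


def calibrate_threshold(det: HaarStumpDetector, images,
                        target_rate: float, **detect_kw) -> float:
    """Set the threshold so the detector fires on about ``target_rate`` of
    the calibration images; returns the new threshold."""
    top = []
    for img in images:
        cand = detect_whole_face(img, det, threshold=-np.inf, group=False,
                                 **detect_kw)
        top.append(cand[0].score if cand else -np.inf)
    det.threshold = float(np.quantile(np.asarray(top), 1.0 - target_rate))
    return det.threshold


# ---------------------------------------------------------------------------
# sliding-window detection


def _default_scales(window: int, image_min_side: int,
                    size_fracs=(0.35, 0.45, 0.55, 0.65, 0.75, 0.85)) -> list[float]:
    """Rescale factors mapping plausible face sizes onto the window."""
    return [window / (f * image_min_side) for f in size_fracs]


def group_detections(boxes: list[BoundingBox], min_iou: float = 0.3,
                     floor: float | None = None) -> list[BoundingBox]:
    """Merge overlapping raw detections into averaged boxes.

    Sliding windows fire in clusters around a true object; each cluster
    is reduced to the mean of its member coordinates weighted by score
    mass above ``floor`` (default: the weakest score present), and is
    scored by that total mass — the neighbour-grouping step of cascade
    detectors, with strong hits dominating the average.
    """
    if not boxes:
        return []
    if floor is None:
        floor = min(b.score for b in boxes)
    clusters: list[list[BoundingBox]] = []
    for b in sorted(boxes, key=lambda b: (-b.score, -b.area, b.x0, b.y0)):
        for cl in clusters:
            if iou(b, cl[0]) >= min_iou:
                cl.append(b)
                break
        else:
            clusters.append([b])
    # stump-sum scores are discrete, so whole clusters can sit exactly at
    # the floor; a per-member offset keeps the mass positive and lets
    # multiplicity decide between otherwise tied clusters
    base = max(b.score - floor for b in boxes)
    unit = base / 10.0 if base > 0 else 1.0
    merged = []
    for cl in clusters:
        w = np.array([b.score - floor + unit for b in cl], dtype=float)
        mass = float(w.sum())
        w = w / mass
        merged.append(BoundingBox(
            int(round(np.dot(w, [b.x0 for b in cl]))),
            int(round(np.dot(w, [b.y0 for b in cl]))),
            int(round(np.dot(w, [b.x1 for b in cl]))),
            int(round(np.dot(w, [b.y1 for b in cl]))),
            score=mass,
        ))
    return merged


def detect_whole_face(
    image: np.ndarray,
    model: HaarStumpDetector,
    *,
    scales: list[float] | None = None,
    stride: int = 2,
    threshold: float | None = None,
    max_boxes: int = 20,
    group: bool = True,
) -> list[BoundingBox]:
    """Multi-scale sliding-window detection; boxes sorted by score
    descending (ties: larger area, then smaller (x0, y0)).  With
    ``group`` (default), overlapping raw hits are merged into averaged
    boxes first."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    h, w = img.shape
    if threshold is None:
        threshold = model.threshold
    if scales is None:
        scales = _default_scales(model.window, min(h, w))
    boxes: list[BoundingBox] = []
    for f in scales:
        sh, sw = max(int(round(h * f)), model.window), max(int(round(w * f)), model.window)
        scaled = resize(img, (sh, sw), anti_aliasing=f < 1.0)
        ii2 = _pad_integral(scaled)
        x, ys, xs = _eval_features_windows(ii2, model.features, model.window, stride)
        if len(x) == 0:
            continue
        scores = model.decision_scores(x).reshape(len(ys), len(xs))
        yy, xx = np.nonzero(scores >= threshold)
        for r, c in zip(yy, xx):
            bx0 = int(round(xs[c] / f))
            by0 = int(round(ys[r] / f))
            bx1 = int(round((xs[c] + model.window) / f))
            by1 = int(round((ys[r] + model.window) / f))
            boxes.append(BoundingBox(bx0, by0, bx1, by1,
                                     float(scores[r, c])).clipped(h, w))
    if group:
        boxes = group_detections(boxes, floor=threshold
                                 if np.isfinite(threshold) else None)
    boxes.sort(key=lambda b: (-b.score, -b.area, b.x0, b.y0))
    return boxes[:max_boxes]


def detect_parts(
    image: np.ndarray,
    eye_model: HaarStumpDetector,
    ear_model: HaarStumpDetector,
    *,
    stride: int = 2,
    scales: list[float] | None = None,
    max_boxes: int = 6,
) -> tuple[list[BoundingBox], list[BoundingBox]]:
    """Independent eye and ear detection; either list may be empty."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    h, w = img.shape

    def run(model: HaarStumpDetector, part_fracs) -> list[BoundingBox]:
        sc = scales or [model.window / (f * min(h, w)) for f in part_fracs]
        return detect_whole_face(img, model, scales=sc, stride=stride,
                                 max_boxes=max_boxes)

    eyes = run(eye_model, (0.08, 0.12, 0.16))
    ears = run(ear_model, (0.12, 0.17, 0.22))
    return eyes, ears


# ---------------------------------------------------------------------------
# geometric plausibility filtering


@dataclass(frozen=True)
class GeometricRules:
    """Heuristic expectations of a typical face, as fractions of image height.

    R1: the ears must be above the eyes (smaller center-y).
    R2: the ear-eye center distance lies in [d_min, d_max] x height.
    R3: if two eyes are present, their center-y difference is <= tol x height.
    """

    d_min: float = 0.05
    d_max: float = 0.6
    tol: float = 0.15


@dataclass(frozen=True)
class PartGroup:
    eye_boxes: tuple[BoundingBox, ...]
    ear_boxes: tuple[BoundingBox, ...]
    accepted: bool
    reason: str | None = None


def geometric_filter(
    eye_boxes: list[BoundingBox],
    ear_boxes: list[BoundingBox],
    rules: GeometricRules,
    image_height: int,
) -> PartGroup:
    """Accept or reject a part group; rejection names the first violated
    rule (R1, R2, R3) or "no parts"."""
    if not eye_boxes and not ear_boxes:
        return PartGroup((), (), False, "no parts")
    if not eye_boxes or not ear_boxes:
        # R1 (ears above eyes) is unsatisfiable with a part class missing
        return PartGroup(tuple(eye_boxes), tuple(ear_boxes), False, "R1")
    eye_cy = [b.center[1] for b in eye_boxes]
    ear_cy = [b.center[1] for b in ear_boxes]
    if not min(ear_cy) < min(eye_cy):
        return PartGroup(tuple(eye_boxes), tuple(ear_boxes), False, "R1")
    eye_c = np.mean([b.center for b in eye_boxes], axis=0)
    ear_c = np.mean([b.center for b in ear_boxes], axis=0)
    dist = float(np.hypot(*(eye_c - ear_c)))
    if not rules.d_min * image_height <= dist <= rules.d_max * image_height:
        return PartGroup(tuple(eye_boxes), tuple(ear_boxes), False, "R2")
    if len(eye_boxes) >= 2:
        ys = sorted(eye_cy)
        if ys[-1] - ys[0] > rules.tol * image_height:
            return PartGroup(tuple(eye_boxes), tuple(ear_boxes), False, "R3")
    return PartGroup(tuple(eye_boxes), tuple(ear_boxes), True)


def select_part_group(
    eye_boxes: list[BoundingBox],
    ear_boxes: list[BoundingBox],
    rules: GeometricRules,
    image_height: int,
    max_candidates: int = 4,
) -> PartGroup:
    """Search sub-groups of the raw part detections for a plausible face.

    Part detectors fire on clutter too, so the full detection set
    rarely passes the geometric filter as-is.  This tries combinations
    of the top-scoring eyes and ears (one or two of each) and returns
    the best accepted group — preferring complete (2-eye, 2-ear)
    groups, then higher total score.  If nothing passes, the filter's
    verdict on the full set is returned (carrying its reason).
    """
    from itertools import combinations

    eyes = eye_boxes[:max_candidates]
    ears = ear_boxes[:max_candidates]
    best: PartGroup | None = None
    best_key = None
    for ne in (2, 1):
        for na in (2, 1):
            for esub in combinations(eyes, min(ne, len(eyes))):
                for asub in combinations(ears, min(na, len(ears))):
                    if not esub or not asub:
                        continue
                    grp = geometric_filter(list(esub), list(asub), rules,
                                           image_height)
                    if grp.accepted:
                        key = (len(esub) + len(asub),
                               sum(b.score for b in (*esub, *asub)))
                        if best_key is None or key > best_key:
                            best, best_key = grp, key
    if best is not None:
        return best
    return geometric_filter(eye_boxes, ear_boxes, rules, image_height)


# ---------------------------------------------------------------------------
# the two-stage pipeline


def two_stage_detect(
    image: np.ndarray,
    face_model: HaarStumpDetector,
    eye_model: HaarStumpDetector | None = None,
    ear_model: HaarStumpDetector | None = None,
    rules: GeometricRules | None = None,
    *,
    parts_margin: float = 0.06,
    stride: int = 2,
    min_quality: float | None = None,
) -> FaceHypothesis:
    """Whole-face detection with part-based fall-back.

    Stage 2 runs if and only if stage 1 returns no box.  A fall-back
    hypothesis' face box is the tight box around the accepted parts,
    expanded by ``parts_margin`` on each side.  ``min_quality``
    optionally enables the sharpness gate: accepted crops whose
    Laplacian-response variance falls below it are rejected (off by
    default — this screening was originally a manual step).
    """
    img = np.asarray(image)
    h, w = img.shape[:2]

    def gated(hyp: FaceHypothesis) -> FaceHypothesis:
        if min_quality is None or not hyp.accepted:
            return hyp
        crop = img[hyp.face_box.y0:hyp.face_box.y1,
                   hyp.face_box.x0:hyp.face_box.x1]
        if laplacian_energy(crop) < min_quality:
            hyp.accepted = False
            hyp.rejection_reason = "low quality"
        return hyp

    face_boxes = detect_whole_face(img, face_model, stride=stride)
    if face_boxes:
        return gated(FaceHypothesis(face_box=face_boxes[0],
                                    source="whole_face", accepted=True))
    if eye_model is None or ear_model is None:
        return FaceHypothesis(face_box=None, source="whole_face",
                              accepted=False, rejection_reason="no detection")
    eyes, ears = detect_parts(img, eye_model, ear_model, stride=stride)
    group = select_part_group(eyes, ears, rules or GeometricRules(), h)
    if not group.accepted:
        return FaceHypothesis(face_box=None, eye_boxes=eyes, ear_boxes=ears,
                              source="parts_fallback", accepted=False,
                              rejection_reason=group.reason)
    parts = [*group.eye_boxes, *group.ear_boxes]
    x0 = min(b.x0 for b in parts)
    y0 = min(b.y0 for b in parts)
    x1 = max(b.x1 for b in parts)
    y1 = max(b.y1 for b in parts)
    # anatomical expansion: the ears already span the face width, and
    # the muzzle extends below the eyes by roughly the ear-eye span
    d = max(y1 - y0, 1)
    mx = int(round(parts_margin * (x1 - x0)))
    box = BoundingBox(x0 - mx, y0 - int(round(0.05 * d)),
                      x1 + mx, y1 + int(round(0.9 * d)),
                      score=float(np.mean([b.score for b in parts]))).clipped(h, w)
    return gated(FaceHypothesis(face_box=box, eye_boxes=list(group.eye_boxes),
                                ear_boxes=list(group.ear_boxes),
                                source="parts_fallback", accepted=True))


def crop_to_hypothesis(image: np.ndarray, hypothesis: FaceHypothesis,
                       margin_frac: float = 0.1) -> np.ndarray:
    """Crop the face box expanded by ``margin_frac`` per side, clipped to
    the image; requires an accepted hypothesis."""
    if not hypothesis.accepted or hypothesis.face_box is None:
        raise ValueError("no face to crop: hypothesis was not accepted")
    img = np.asarray(image)
    h, w = img.shape[:2]
    b = hypothesis.face_box
    mx = int(round(margin_frac * (b.x1 - b.x0)))
    my = int(round(margin_frac * (b.y1 - b.y0)))
    x0, y0 = max(b.x0 - mx, 0), max(b.y0 - my, 0)
    x1, y1 = min(b.x1 + mx, w), min(b.y1 + my, h)
    return img[y0:y1, x0:x1]


def laplacian_energy(image: np.ndarray) -> float:
    """Variance of the Laplacian response — the optional quality gate's
    sharpness statistic (low values indicate blur or empty crops)."""
    return float(np.var(ndimage.laplace(np.asarray(image, dtype=float))))


def detection_report(hypotheses: list[FaceHypothesis]) -> pd.DataFrame:
    """Per-stage and overall acceptance rates (exact rationals, formatted
    only in the returned table)."""
    if not hypotheses:
        raise ValueError("no detection records")
    total = len(hypotheses)
    stage1 = [h for h in hypotheses if h.source == "whole_face"]
    stage2 = [h for h in hypotheses if h.source == "parts_fallback"]
    s1_acc = sum(h.accepted for h in stage1)
    s2_acc = sum(h.accepted for h in stage2)
    overall = Fraction(s1_acc + s2_acc, total)
    rows = [
        {"stage": "whole_face", "n": total, "accepted": s1_acc,
         "rate": float(Fraction(s1_acc, total))},
        {"stage": "parts_fallback", "n": len(stage2), "accepted": s2_acc,
         "rate": float(Fraction(s2_acc, len(stage2))) if stage2 else float("nan")},
        {"stage": "overall", "n": total, "accepted": s1_acc + s2_acc,
         "rate": float(overall)},
    ]
    return pd.DataFrame(rows)
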