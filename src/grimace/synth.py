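"""Synthetic mouse-face image generator with ground-truth geometry.

Emulates the structure of a post-anesthesia/post-surgery image study of
black-furred mice: dark faces photographed against a light cage
background, one image series per animal per acquisition time point, and
latent grimace action-unit intensities (orbital tightening, nose bulge,
cheek bulge, ear position, whisker change; each on the 0-2 scale of the
Mouse Grimace Scale) whose means depend on treatment and time.  The
point is not photorealism — faces are built from filled ellipses and
line strokes — but that every downstream stage (detection, labeling,
subject-disjoint splitting, classification, relevance maps) can be
exercised and validated against known ground truth.

Key emulated structure:

* per-animal nuisance identity (face size, fur darkness, eye spacing,
  ear size, whisker angle) held fixed across all images of one animal,
  so subject-disjoint splitting is a meaningful test;
* treatment-dependent action-unit time profiles: at "effect" time
  points the latent means are raised by a configurable margin over the
  baseline/no-effect level; untreated animals always show the baseline
  profile;
* action units drive the rendering monotonically: orbital tightening
  narrows the drawn eye opening, ear position drops and spreads the
  ears, whisker change rotates the whisker strokes, nose and cheek
  bulges enlarge/brighten their regions.

All randomness flows from a single seed fanned out by stable hashing,
so any subset of the dataset is reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .labeling import ACTION_UNITS, TIME_GRID, assign_binary_label
from .utils import stable_seed

__all__ = [
    "AnimalIdentity",
    "ActionUnitState",
    "SceneParams",
    "GroundTruthGeometry",
    "DatasetConfig",
    "SyntheticDataset",
    "stable_seed",
    "sample_time_profile",
    "render_face",
    "generate_dataset",
    "face_scene",
    "cage_scene",
]

TREATMENTS = ("IN", "KXN", "C", "untreated")
SEXES = ("female", "male")


@dataclass(frozen=True)
class AnimalIdentity:
    """Per-animal nuisance traits, fixed across all images of the animal."""

    animal_id: str
    sex: str
    treatment: str
    face_size_px: float
    fur_darkness: float          # 0 light .. 1 darkest
    eye_spacing_px: float
    ear_size_px: float
    baseline_whisker_angle_deg: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not 0.0 <= self.fur_darkness <= 1.0:
            raise ValueError("fur_darkness must be in [0, 1]")


@dataclass(frozen=True)
class ActionUnitState:
    """Latent intensities of the five grimace action units, each in [0, 2]."""

    orbital_tightening: float
    nose_bulge: float
    cheek_bulge: float
    ear_position: float
    whisker_change: float

    def __post_init__(self) -> None:
        for name in ACTION_UNITS:
            v = getattr(self, name)
            if not 0.0 <= v <= 2.0:
                raise ValueError(f"{name}={v} outside [0, 2]")

    @property
    def mean_score(self) -> float:
        return float(np.mean([getattr(self, u) for u in ACTION_UNITS]))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, u) for u in ACTION_UNITS], dtype=float)


@dataclass(frozen=True)
class PoseJitter:
    max_translate_px: float = 3.0
    max_rotate_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.max_translate_px < 0 or self.max_rotate_deg < 0:
            raise ValueError("jitter ranges must be non-negative")


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for one scene."""

    image_size: tuple[int, int] = (64, 64)   # (H, W)
    background_brightness: float = 0.82
    pose_jitter: PoseJitter = field(default_factory=PoseJitter)
    blur_sigma: float = 0.6
    pellet_count: int = 0
    noise_sd: float = 0.02                   # fraction of full scale
    #: fraction of the lower face hidden by a foreground occluder (e.g.
    #: bedding or cage furniture in front of a freely moving mouse);
    #: eyes and ears stay visible, so part detection remains possible
    occlusion_frac: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image_size must be at least 64x64")
        if not 0.0 <= self.background_brightness <= 1.0:
            raise ValueError("background_brightness must be in [0, 1]")
        if self.blur_sigma < 0 or self.noise_sd < 0 or self.pellet_count < 0:
            raise ValueError("blur_sigma, noise_sd, pellet_count must be >= 0")
        if not 0.0 <= self.occlusion_frac <= 0.6:
            raise ValueError("occlusion_frac must be in [0, 0.6]")


Box = tuple[int, int, int, int]  # (x0, y0, x1, y1), 0-based half-open


@dataclass(frozen=True)
class GroundTruthGeometry:
    """Pixel bounding boxes of the drawn face and its parts.

    Convention: 0-based, half-open [x0, x1) x [y0, y1), y down.  In the
    rendered canonical pose the ear box vertical centers lie strictly
    above the eye box vertical centers.
    """

    face_box: Box
    left_eye_box: Box
    right_eye_box: Box
    left_ear_box: Box
    right_ear_box: Box
    nose_box: Box

    def part_boxes(self) -> dict[str, Box]:
        return {
            "left_eye": self.left_eye_box,
            "right_eye": self.right_eye_box,
            "left_ear": self.left_ear_box,
            "right_ear": self.right_ear_box,
            "nose": self.nose_box,
        }


def face_scene(size: int = 64, **kw) -> SceneParams:
    """Scene preset for tight face crops (classifier input)."""
    return SceneParams(image_size=(size, size), **kw)


def cage_scene(size: int = 96, pellet_count: int = 3, **kw) -> SceneParams:
    """Scene preset with background clutter (detector input)."""
    return SceneParams(image_size=(size, size), pellet_count=pellet_count, **kw)


# ---------------------------------------------------------------------------
# action-unit time profiles


def sample_time_profile(
    treatment: str,
    time_label: str,
    *,
    margin: float = 1.0,
    baseline_mean: float = 0.3,
    unit_sd: float = 0.25,
    signature: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution parameters (per-unit mean, sd) of the latent action units.

    At time points labelled "effect" for the treatment, the mean of each
    action unit is ``baseline_mean + margin * signature[unit]``; at all
    other times (and always for untreated animals) it is ``baseline_mean``.
    ``signature`` defaults to 1.0 for every unit, i.e. a uniform grimace
    response; distinct per-treatment signatures model treatment-specific
    facial expressions.  Means are clipped to [0, 2].
    """
    if treatment not in TIME_GRID:
        raise ValueError(f"unknown treatment {treatment!r}")
    if time_label not in TIME_GRID[treatment]:
        raise ValueError(
            f"unknown time label {time_label!r} for treatment {treatment!r}; "
            f"expected one of {sorted(TIME_GRID[treatment])}")
    label = assign_binary_label(treatment, time_label)
    sig = {u: 1.0 for u in ACTION_UNITS}
    if signature:
        unknown = set(signature) - set(ACTION_UNITS)
        if unknown:
            raise ValueError(f"unknown action units in signature: {sorted(unknown)}")
        sig.update(signature)
    bump = margin if label == "effect" else 0.0
    means = np.clip(
        [baseline_mean + bump * sig[u] for u in ACTION_UNITS], 0.0, 2.0)
    sds = np.full(len(ACTION_UNITS), unit_sd, dtype=float)
    return means, sds


def sample_state(
    treatment: str,
    time_label: str,
    rng: np.random.Generator,
    **profile_kw,
) -> ActionUnitState:
    """Draw one action-unit state from the treatment/time profile
    (Gaussian per unit, truncated to [0, 2] by clipping)."""
    means, sds = sample_time_profile(treatment, time_label, **profile_kw)
    vals = np.clip(rng.normal(means, sds), 0.0, 2.0)
    return ActionUnitState(*vals)


# ---------------------------------------------------------------------------
# rendering


def _ellipse_mask(h: int, w: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return ((xx - cx) / max(rx, 1e-6)) ** 2 + ((yy - cy) / max(ry, 1e-6)) ** 2 <= 1.0


def _box_of(cx: float, cy: float, rx: float, ry: float) -> Box:
    return (int(np.floor(cx - rx)), int(np.floor(cy - ry)),
            int(np.ceil(cx + rx)) + 1, int(np.ceil(cy + ry)) + 1)


def _union(*boxes: Box) -> Box:
    xs0, ys0, xs1, ys1 = zip(*boxes)
    return (min(xs0), min(ys0), max(xs1), max(ys1))


def render_face(
    identity: AnimalIdentity,
    state: ActionUnitState,
    scene: SceneParams,
    rng_seed: int,
) -> tuple[np.ndarray, GroundTruthGeometry]:
    """Render one grayscale face image plus its ground-truth geometry.

    A pure function of its arguments: the same call yields bitwise
    identical output.  Returns ``(image, geometry)`` where image is a
    (H, W) uint8 array in [0, 255].
    """
    rng = np.random.default_rng(rng_seed)
    h, w = scene.image_size
    img = np.full((h, w), scene.background_brightness * 255.0, dtype=np.float32)
    # mild vertical illumination gradient, as from overhead light
    img += np.linspace(6.0, -6.0, h, dtype=np.float32)[:, None]

    jit = scene.pose_jitter
    dx = rng.uniform(-jit.max_translate_px, jit.max_translate_px)
    dy = rng.uniform(-jit.max_translate_px, jit.max_translate_px)
    theta = np.deg2rad(rng.uniform(-jit.max_rotate_deg, jit.max_rotate_deg))
    cx, cy = w / 2.0 + dx, h / 2.0 + dy
    R = identity.face_size_px / 2.0

    def place(ox: float, oy: float) -> tuple[float, float]:
        """Rotate a face-frame offset by the pose angle, then translate."""
        rx = ox * np.cos(theta) - oy * np.sin(theta)
        ry = ox * np.sin(theta) + oy * np.cos(theta)
        return cx + rx, cy + ry

    au = state
    fur = (0.10 + 0.16 * (1.0 - identity.fur_darkness)) * 255.0

    # head
    head_rx, head_ry = R, 0.92 * R
    img[_ellipse_mask(h, w, cx, cy, head_rx, head_ry)] = fur
    head_box = _box_of(cx, cy, head_rx, head_ry)

    # cheeks: brighter patches that grow with cheek bulge
    cheek_r = 0.26 * R * (1.0 + 0.3 * au.cheek_bulge)
    for sx in (-1, 1):
        ccx, ccy = place(sx * 0.45 * R, 0.30 * R)
        img[_ellipse_mask(h, w, ccx, ccy, cheek_r, 0.8 * cheek_r)] = (
            fur + 24.0 * au.cheek_bulge)

    # ears: drop and spread with ear_position
    ear_r = identity.ear_size_px
    ear_boxes = []
    for sx in (-1, 1):
        ex = sx * (0.58 * R + 0.18 * R * (au.ear_position / 2.0))
        ey = -0.58 * R + 0.30 * R * (au.ear_position / 2.0)
        ecx, ecy = place(ex, ey)
        img[_ellipse_mask(h, w, ecx, ecy, ear_r, ear_r)] = fur + 18.0
        img[_ellipse_mask(h, w, ecx, ecy, 0.55 * ear_r, 0.55 * ear_r)] = fur - 8.0
        ear_boxes.append(_box_of(ecx, ecy, ear_r, ear_r))

    # eyes: bright (shiny); orbital tightening narrows the opening
    eye_rx = 0.16 * R
    eye_ry = max(0.8, 0.12 * R * (1.0 - 0.35 * au.orbital_tightening))
    eye_boxes = []
    for sx in (-1, 1):
        ecx, ecy = place(sx * identity.eye_spacing_px / 2.0, -0.08 * R)
        img[_ellipse_mask(h, w, ecx, ecy, eye_rx, eye_ry)] = 150.0
        eye_boxes.append(_box_of(ecx, ecy, eye_rx, eye_ry))

    # nose: bright tip that enlarges with nose bulge
    nose_r = 0.10 * R * (1.0 + 0.45 * au.nose_bulge)
    ncx, ncy = place(0.0, 0.55 * R)
    img[_ellipse_mask(h, w, ncx, ncy, nose_r, 0.8 * nose_r)] = 175.0
    nose_box = _box_of(ncx, ncy, nose_r, 0.8 * nose_r)

    # whiskers: strokes rotating backwards/down with whisker_change
    base_angle = np.deg2rad(identity.baseline_whisker_angle_deg)
    extra = np.deg2rad(32.0) * (au.whisker_change / 2.0)
    t = np.linspace(0.0, 1.0, 50)
    for sx in (-1, 1):
        px, py = sx * 0.28 * R, 0.42 * R
        for k in (-1, 0, 1):
            ang = base_angle + extra + 0.16 * k
            wx = px + sx * t * 0.55 * R * np.cos(ang)
            wy = py + t * 0.55 * R * np.sin(ang) + k * 0.05 * R
            pts = [place(ox, oy) for ox, oy in zip(wx, wy)]
            xs = np.clip(np.round([p[0] for p in pts]).astype(int), 0, w - 1)
            ys = np.clip(np.round([p[1] for p in pts]).astype(int), 0, h - 1)
            img[ys, xs] = 205.0

    # background clutter: food pellets away from the face
    face_box = _union(head_box, *ear_boxes)
    for _ in range(scene.pellet_count):
        for _attempt in range(20):
            pcx, pcy = rng.uniform(4, w - 4), rng.uniform(4, h - 4)
            pr = rng.uniform(2.0, 3.5)
            if not (face_box[0] - pr < pcx < face_box[2] + pr
                    and face_box[1] - pr < pcy < face_box[3] + pr):
                img[_ellipse_mask(h, w, pcx, pcy, pr, 0.8 * pr)] = 95.0
                break

    if scene.occlusion_frac > 0:
        # foreground occluder over the lower face; eyes/ears stay visible
        x0f, y0f, x1f, y1f = face_box
        cut = int(round((y1f - y0f) * scene.occlusion_frac))
        img[max(y1f - cut, 0):y1f, max(x0f - 2, 0):min(x1f + 2, w)] = (
            scene.background_brightness * 255.0 - 20.0)

    if scene.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, scene.blur_sigma)
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd * 255.0, img.shape)

    geometry = GroundTruthGeometry(
        face_box=face_box,
        left_eye_box=eye_boxes[0],
        right_eye_box=eye_boxes[1],
        left_ear_box=ear_boxes[0],
        right_ear_box=ear_boxes[1],
        nose_box=nose_box,
    )
    fb = geometry.face_box
    if fb[0] < 0 or fb[1] < 0 or fb[2] > w or fb[3] > h:
        raise ValueError(
            f"face (box {fb}) does not fit in a {h}x{w} image; reduce "
            "face_size_px or pose jitter, or enlarge the scene")
    return np.clip(img, 0, 255).astype(np.uint8), geometry


# ---------------------------------------------------------------------------
# dataset generation


@dataclass(frozen=True)
class DatasetConfig:
    """Counts and distributions for one synthetic study.

    ``animals`` maps treatment -> number of animals; every animal is
    imaged ``images_per_time`` times at every time point of its
    treatment's acquisition grid.  ``effect_margin`` is the latent
    action-unit mean difference between effect and no-effect time
    points; ``signatures`` optionally gives each treatment its own
    action-unit response pattern.
    """

    animals: dict[str, int] = field(
        default_factory=lambda: {"IN": 4, "KXN": 4, "C": 4, "untreated": 2})
    images_per_time: int = 3
    time_labels: dict[str, tuple[str, ...]] | None = None
    effect_margin: float = 1.0
    baseline_mean: float = 0.3
    unit_sd: float = 0.25
    animal_sd: float = 0.1        # per-animal random shift of unit means
    signatures: dict[str, dict[str, float]] | None = None
    scene: SceneParams = field(default_factory=SceneParams)
    face_size_range: tuple[float, float] = (0.58, 0.72)  # fraction of min(H, W)

    def __post_init__(self) -> None:
        for tr, n in self.animals.items():
            if tr not in TREATMENTS:
                raise ValueError(f"unknown treatment {tr!r}")
            if n < 1:
                raise ValueError("animal counts must be >= 1")
        if self.images_per_time < 1:
            raise ValueError("images_per_time must be >= 1")


@dataclass
class SyntheticDataset:
    """In-memory synthetic study: metadata table, images, geometry."""

    frame: pd.DataFrame
    images: list[np.ndarray]
    geometry: pd.DataFrame
    identities: dict[str, AnimalIdentity]

    def write(self, outdir) -> None:
        """Write PNG images plus metadata.csv / geometry.csv."""
        from pathlib import Path

        from PIL import Image

        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        for path, arr in zip(self.frame["image_path"], self.images):
            Image.fromarray(arr).save(outdir / path)
        self.frame.to_csv(outdir / "metadata.csv", index=False)
        self.geometry.to_csv(outdir / "geometry.csv", index=False)


def _sample_identity(animal_id: str, sex: str, treatment: str,
                     cfg: DatasetConfig, rng: np.random.Generator) -> AnimalIdentity:
    h, w = cfg.scene.image_size
    lo, hi = cfg.face_size_range
    face = rng.uniform(lo, hi) * min(h, w)
    return AnimalIdentity(
        animal_id=animal_id,
        sex=sex,
        treatment=treatment,
        face_size_px=face,
        fur_darkness=rng.uniform(0.55, 1.0),
        eye_spacing_px=rng.uniform(0.52, 0.66) * face,
        ear_size_px=rng.uniform(0.24, 0.32) * face / 2.0,
        baseline_whisker_angle_deg=rng.uniform(-8.0, 8.0),
    )


def generate_dataset(config: DatasetConfig, seed: int) -> SyntheticDataset:
    """Generate a full synthetic study.

    One identity per animal; per (animal, time point) one shared latent
    action-unit state and ``images_per_time`` independently jittered
    renders of it.  The metadata table carries provenance, the latent
    per-unit intensities, their mean, and the derived binary label; the
    geometry table carries one row of box coordinates per image.
    """
    rows = []
    geo_rows = []
    images: list[np.ndarray] = []
    identities: dict[str, AnimalIdentity] = {}
    sig = config.signatures or {}
    for treatment in sorted(config.animals):
        n_animals = config.animals[treatment]
        grid = (config.time_labels or TIME_GRID)[treatment]
        for a in range(n_animals):
            animal_id = f"{treatment}_{a:03d}"
            arng = np.random.default_rng(stable_seed(seed, "animal", animal_id))
            sex = SEXES[a % 2]
            ident = _sample_identity(animal_id, sex, treatment, config, arng)
            identities[animal_id] = ident
            shift = arng.normal(0.0, config.animal_sd, len(ACTION_UNITS))
            for time_label in grid:
                srng = np.random.default_rng(
                    stable_seed(seed, "state", animal_id, time_label))
                means, sds = sample_time_profile(
                    treatment, time_label,
                    margin=config.effect_margin,
                    baseline_mean=config.baseline_mean,
                    unit_sd=config.unit_sd,
                    signature=sig.get(treatment),
                )
                vals = np.clip(srng.normal(means + shift, sds), 0.0, 2.0)
                state = ActionUnitState(*vals)
                for i in range(config.images_per_time):
                    img_seed = stable_seed(seed, "image", animal_id, time_label, i)
                    img, geo = render_face(ident, state, config.scene, img_seed)
                    path = f"images/{animal_id}_{time_label}_{i:02d}.png"
                    row = {
                        "image_path": path,
                        "animal_id": animal_id,
                        "sex": sex,
                        "treatment": treatment,
                        "time_label": time_label,
                        "binary_label": assign_binary_label(treatment, time_label),
                        "mean_latent_score": state.mean_score,
                    }
                    for u in ACTION_UNITS:
                        row[u] = getattr(state, u)
                    rows.append(row)
                    images.append(img)
                    grow = {"image_path": path}
                    for name, box in [("face", geo.face_box),
                                      *geo.part_boxes().items()]:
                        x0, y0, x1, y1 = box
                        grow.update({f"{name}_x0": x0, f"{name}_y0": y0,
                                     f"{name}_x1": x1, f"{name}_y1": y1})
                    geo_rows.append(grow)
    frame = pd.DataFrame(rows)
    geometry = pd.DataFrame(geo_rows)
    return SyntheticDataset(frame=frame, images=images, geometry=geometry,
                            identities=identities)
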