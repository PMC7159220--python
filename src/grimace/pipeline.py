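"""Pipeline orchestration: synthesize -> detect/crop -> split -> train ->
evaluate -> explain, from a single configuration file.

A run directory receives per-stage artifacts plus ``manifest.json``
recording configuration, seeds and per-stage input/output counts, so a
run is reproducible from its manifest on the same backend version.  A
failing stage halts the run; the CLI maps that to a non-zero exit
status naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as gio
from .classifier import TrainConfig, build_own_cnn, preprocess_batch
from .detection import GeometricRules, crop_to_hypothesis, two_stage_detect
from .evaluation import cross_validate
from .explain import dtd_relevance, render_heatmap
from .labeling import leave_one_animal_out, subject_kfold
from .synth import DatasetConfig, SceneParams, generate_dataset
from .utils import stable_seed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from a YAML mapping."""

    out_dir: str = "run"
    seed: int = 0
    # synthesis
    animals: dict = field(default_factory=lambda: {"KXN": 6})
    images_per_time: int = 3
    time_labels: dict | None = None
    effect_margin: float = 1.0
    image_size: int = 64
    # detection stage (off by default: inputs may already be face crops)
    run_detection: bool = False
    crop_margin: float = 0.1
    # training / evaluation
    scheme: str = "kfold"            # or "loao"
    k: int = 3
    epochs: int = 10
    input_size: int = 32
    average_by_group: bool = True
    # explanation
    run_explain: bool = False
    n_heatmaps: int = 4

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return PipelineConfig(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": []}

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, "time": time.time(), **info})
        logger.info("stage %s: %s", stage, info)

    # -- synthesize ---------------------------------------------------------
    try:
        cfg = DatasetConfig(
            animals=config.animals,
            images_per_time=config.images_per_time,
            time_labels={k: tuple(v) for k, v in config.time_labels.items()}
            if config.time_labels else None,
            effect_margin=config.effect_margin,
            scene=SceneParams(image_size=(config.image_size, config.image_size)),
        )
        ds = generate_dataset(cfg, stable_seed(config.seed, "synth"))
        ds.write(out)
        record("synth", images_out=len(ds.images),
               metadata_sha256=_sha256(out / "metadata.csv"),
               seed=stable_seed(config.seed, "synth"))
    except Exception as e:  # noqa: BLE001 - halting contract
        raise PipelineError("synth", str(e)) from e

    records = ds.frame
    images = ds.images

    # -- detect and crop ----------------------------------------------------
    if config.run_detection:
        try:
            from .experiments import train_synthetic_detectors

            face, eye, ear = train_synthetic_detectors(
                stable_seed(config.seed, "detectors"))
            kept_rows, crops = [], []
            hyp_info = []
            for i, img in enumerate(images):
                hyp = two_stage_detect(img, face, eye, ear, GeometricRules())
                hyp_info.append(hyp)
                if hyp.accepted:
                    kept_rows.append(i)
                    crops.append(crop_to_hypothesis(img, hyp, config.crop_margin))
            records = records.iloc[kept_rows].reset_index(drop=True).copy()
            records["detection_source"] = [
                hyp_info[i].source for i in kept_rows]
            images = crops
            record("detect", images_in=len(hyp_info), faces_accepted=len(crops))
            if not crops:
                raise ValueError("no face hypotheses accepted")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("detect", str(e)) from e

    # -- split --------------------------------------------------------------
    try:
        if config.scheme == "kfold":
            folds = subject_kfold(records, config.k,
                                  stable_seed(config.seed, "split"))
        elif config.scheme == "loao":
            folds = leave_one_animal_out(records)
        else:
            raise ValueError(f"unknown split scheme {config.scheme!r}")
        from .labeling import folds_to_frame

        folds_to_frame(folds).to_csv(out / "folds.csv", index=False)
        record("split", scheme=config.scheme, folds=len(folds),
               animals=records["animal_id"].nunique())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("split", str(e)) from e

    # -- train + evaluate ---------------------------------------------------
    try:
        tc = TrainConfig(input_size=(config.input_size, config.input_size),
                         epochs=config.epochs,
                         seed=stable_seed(config.seed, "train"))
        x = preprocess_batch(images, tc)

        def builder(s):
            return build_own_cnn(tc.input_size, seed=s)

        res = cross_validate(records, x, folds, builder, tc,
                             average=config.average_by_group,
                             seed=stable_seed(config.seed, "cv"))
        results = {
            "per_fold": [m.as_dict() for m in res.per_fold],
            "summary": res.summary,
        }
        if res.summary_grouped is not None:
            results["per_fold_grouped"] = [m.as_dict() for m in res.per_fold_grouped]
            results["summary_grouped"] = res.summary_grouped
        (out / "results.json").write_text(json.dumps(results, indent=2))
        record("evaluate", records_trained_on=len(records), folds=len(folds),
               accuracy_mean=res.summary["accuracy"][0])
    except Exception as e:  # noqa: BLE001
        raise PipelineError("train", str(e)) from e

    # -- explain ------------------------------------------------------------
    if config.run_explain:
        try:
            from PIL import Image

            tc = TrainConfig(input_size=(config.input_size, config.input_size),
                             epochs=config.epochs,
                             seed=stable_seed(config.seed, "train"))
            x = preprocess_batch(images, tc)
            model = build_own_cnn(tc.input_size,
                                  seed=stable_seed(config.seed, "explain-model"))
            from .classifier import train as train_model

            train_model(model, x, records["binary_label"].to_numpy(), tc)
            hm_dir = out / "heatmaps"
            hm_dir.mkdir(exist_ok=True)
            n = min(config.n_heatmaps, len(x))
            made = 0
            for i in range(n):
                try:
                    rm = dtd_relevance(model, x[i])
                except ValueError:
                    continue  # negative activation: nothing to decompose
                panel = render_heatmap(rm, x[i][:, :, 0], "side_by_side")
                Image.fromarray(panel).save(hm_dir / f"heatmap_{i:03d}.png")
                made += 1
            record("explain", heatmaps=made)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("explain", str(e)) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
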