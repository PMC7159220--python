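# grimace

Automated recognition of post-anesthetic and post-surgical effects from
face images of black-furred laboratory mice.

Assessing the well-being of laboratory mice is central to refinement
under the 3R principle, and the Mouse Grimace Scale (MGS) — five facial
action units (orbital tightening, nose bulge, cheek bulge, ear
position, whisker change), each scored 0–2 — is the standard
image-based tool. Manual MGS scoring is slow and requires trained
raters, so this package implements a two-component pipeline that does
the job automatically:

1. **Face detection.** A whole-face detector based on boosted cascades
   of simple (Haar-like rectangle) features scans the image over a
   multi-scale sliding window. When it finds nothing, a fall-back stage
   runs separate eye and ear detectors and keeps groups of parts that
   satisfy geometric expectations of a typical face (most importantly,
   the ears must be above the eyes). Accepted faces are cropped with a
   configurable margin.
2. **Binary facial-expression classification.** Each cropped face is
   classified as showing a *post-anesthetic/surgical effect* or not.
   Two classifier paths are provided: a frozen convolutional base with
   a single fully connected softmax layer on top (transfer-learning
   path), and a small convolutional network trained from scratch —
   three 3×3 convolutions with 32, 32 and 64 filters, two fully
   connected layers of 128 units, and a 2-way softmax. Training uses
   Adam (learning rate 0.001, β₁ 0.9, β₂ 0.999, ε 1e-07, no decay) on
   the categorical cross-entropy, batch size 100, 50 epochs with a
   fresh permutation per epoch, inputs resized to 224×224 bilinearly;
   classes are balanced by sub-sampling.

Labels come from the treatment and acquisition time of each image:
isoflurane anesthesia (IN) marks 30 min post-procedure as "effect";
ketamine/xylazine anesthesia (KXN) marks 30 and 150 min; castration (C)
marks 30, 150 and 300 min; baselines, later time points and untreated
animals are "no effect".

Evaluation is strictly **subject-disjoint**: animals, not images, are
split into cross-validation folds (10-fold, or leave-one-animal-out for
small cohorts), so no mouse contributes images to both training and
test sets. Reported metrics are accuracy, sensitivity (TPR) and
specificity (TNR) with "effect" as the positive class, as mean ±
standard deviation over folds. Classification can additionally be
aggregated per (animal, time point) by averaging softmax confidence
vectors over all images of that group — the analysis that raises
performance substantially. Cross-treatment transfer (train on one
procedure, test on another) and deep Taylor decomposition heatmaps (the
per-pixel relevance of a prediction, propagated backwards through the
network) round out the analysis.

Because the original image corpus is an external download, the package
ships a **synthetic face-image generator**: primitive-rendered mouse
faces on light cage backgrounds with per-animal identity nuisance,
treatment- and time-dependent latent action-unit intensities, and exact
ground-truth bounding boxes for face, eyes, ears and nose. Every stage
of the pipeline is developed and tested end to end against this
generator.

## Worked example

```python
from grimace.experiments import make_recognition_dataset, recovery_run

# a scaled-down recognition study: 12 animals, 4 images per time point
ds = make_recognition_dataset(seed=7, n_animals=12, images_per_time=4)
res = recovery_run(ds, seed=7, epochs=15)
print(f"per-image accuracy:      {res.accuracy:.3f}")
print(f"group-averaged accuracy: {res.grouped_accuracy:.3f}")
```

prints

```
per-image accuracy:      0.833
group-averaged accuracy: 1.000
```

Each of the 12 synthetic animals is imaged 4 times at baseline and 4
times at 30 min post-procedure; a model trained on 9 animals classifies
the 24 images of the 3 held-out animals. 83% of individual images are
classified correctly; averaging the confidence vectors over the 4
images of each (animal, time) group before deciding classifies all 6
groups correctly — the same per-group improvement the pipeline is
designed to exploit on real data.

The command line mirrors the pipeline stages:

```sh
grimace synth --out data --seed 7 --animals KXN=6,IN=4
grimace split --meta data/metadata.csv --scheme kfold --k 5 --out folds.csv
grimace train --meta data/metadata.csv --images data --size 64 --out model
grimace predict --model model --meta data/metadata.csv --images data \
        --average-by animal_id,time_label --out preds.csv
grimace pipeline --config run.yaml   # all stages from one config file
```

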