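# Methods

This note documents the models and procedures the package implements,
the synthetic data they are validated on, and the numerical and design
choices made where the design was genuinely open.

## Binary labels

The label function maps (treatment, acquisition time) to
{effect, no_effect}. Effect time points per procedure: IN (isoflurane
anesthesia) 30 min; KXN (ketamine/xylazine anesthesia) 30 and
150 min; C (castration) 30, 150 and 300 min. Baseline images, later
time points, and untreated animals are no_effect. The acquisition
grids are IN {baseline, 30min, 150min}; KXN {baseline, 30min, 150min,
day2, day9}; C {baseline, 30min, 150min, 300min, day2, day3, day7};
untreated animals share the union grid. Any pair outside this
vocabulary is a hard error — silent defaulting would corrupt ground
truth invisibly.

## Synthetic face generator

The generator emulates the *structure* of a post-procedure image study
of black-furred mice, not its appearance. Faces are drawn from
primitives (filled ellipses for head, ears, eyes, cheeks and nose;
line strokes for whiskers) on a light background with food-pellet
clutter, Gaussian blur and additive noise. Photorealism is explicitly
a non-goal; what matters is that the pipeline is exercisable and that
ground truth (part bounding boxes, latent states, identities) is exact.

* **Latent action units.** Each of the five grimace action units is a
  latent intensity in [0, 2]. At effect time points the per-unit mean
  is `baseline_mean + margin * signature[unit]` (defaults:
  baseline 0.3, margin 1.0, signature 1 for every unit); at no-effect
  times it is the baseline. Draws are Gaussian (sd 0.25 per unit plus
  a per-animal random shift, sd 0.1) truncated to [0, 2] by clipping.
  One state is drawn per (animal, time point) and shared by that
  group's images — a series shot within minutes sees one expression
  state — so group-level confidence averaging has real signal to
  average over.
* **Monotonic rendering.** Orbital tightening shrinks the drawn
  eye-opening height (factor 1 − 0.35·AU); ear position drops and
  spreads the ears (up to 0.30/0.18 of the face radius); nose and
  cheek bulges enlarge/brighten their regions; whisker change rotates
  the whisker strokes by up to 32°. Amplitudes were set so that each
  unit alone is discriminable by the small CNN at the package's
  working resolutions — a requirement for the cross-treatment
  analysis, where treatments express *disjoint* unit signatures.
* **Identity nuisance.** Per-animal face size, fur darkness, eye
  spacing, ear size and baseline whisker angle are fixed across all of
  an animal's images. With margin 0 the classes are identical but
  animals still differ (e.g. in mean intensity), so subject-disjoint
  splitting is a meaningful test: an image-level split would let a
  model score by recognizing individuals.
* **Determinism.** One global seed fans out to per-animal, per-state
  and per-image sub-seeds through blake2b hashing, so any subset of a
  dataset is reproducible independently of generation order.
* **Occlusion.** Scenes can hide the lower face behind a
  background-colored occluder (bedding/furniture in front of a freely
  moving mouse). Eyes and ears stay visible; this is the regime in
  which whole-face detection legitimately fails and the part-based
  fall-back earns its keep.

What passing tests on this generator do **not** show: robustness to
real fur texture, lighting, motion blur, extreme poses or camera
artifacts. The generator validates the pipeline's logic and its
statistical machinery, not field performance.

## Detection

Stage 1 is a boosted ensemble of decision stumps over Haar-like
rectangle features (all five standard types, geometry enumerated by
scikit-image, rectangle sums via integral images), evaluated on a
multi-scale sliding window (stride 2; window/face-size ratios 0.35 to
0.85 of the shorter image side). Stumps are fitted by gradient
boosting (depth-1 trees, learning rate 0.3, subsample 0.8); the window
score is the additive raw (log-odds) score. Gradient boosting is used
rather than discrete adaboost because a perfectly separating single
feature — common on easy synthetic crops — stops adaboost after one
stump and leaves a two-valued score with no localization granularity.

Raw hits are merged by neighbour grouping: overlapping detections
(IoU ≥ 0.3) form clusters; each cluster is reduced to its
score-mass-weighted mean box and ranked by total mass, so strength and
multiplicity both count. Detector training uses, besides random
background crops, *hard negatives*: partially overlapping shifted
crops, loosely framed crops, aspect-preserving upper-face squares, and
occluded faces — these force the ensemble to encode framing and
completeness, which is what makes the top cluster localize well and
occluded faces score low. The stage-1 operating threshold is
calibrated on sliding-window top scores of the clean training scenes
(every clean training scene passes) and raised to the 75th percentile
of occluded-scene top scores if that is higher.

Stage 2 (only when stage 1 returns nothing) runs eye and ear detectors
and searches sub-groups (one or two of each part, from the top four
candidates) for one passing the geometric filter:

* **R1** — every accepted group must have its highest ear center above
  the highest eye center ("above" = smaller y; anchor point is the box
  center, since the rule's anchor is not otherwise determined);
* **R2** — the mean-ear to mean-eye center distance lies within
  [0.05, 0.6] of the image height;
* **R3** — two eyes may differ in center height by at most 0.15 of the
  image height.

R2/R3 bounds are configurable conservative defaults; R1 is the
essential anatomical constraint. Rejections name the first violated
rule. The fall-back face box spans the accepted parts, extended
downward by 0.9× the ear–eye span (the muzzle lies below the eyes) and
by 6% margins elsewhere. An optional quality gate (variance of the
Laplacian response below a threshold rejects blurry crops) is off by
default — in the original workflow this screening was manual.

## Classification

The from-scratch network is conv3×3×32 → conv3×3×32 → conv3×3×64, each
followed by a rectifier and 2×2 max-downsampling, then FC128 → FC128 →
2-way softmax. Pooling placement and activations are a minimal
completion of the stated filter counts and are recorded here as an
assumption. The transfer path classifies frozen convolutional-base
features with a single softmax layer (2·d+2 parameters for feature
dimension d). ImageNet-pretrained bases (ResNet50, InceptionV3) are
name-reserved but require externally supplied weights; the package
ships a frozen random-weight stub backbone (labelled synthetic) that
exercises the identical code path — random frozen convolutional
features are a weak but legitimate representation, and the contract
(backbone weights bit-identical before and after head training) is
tested against it.

Training: Adam exactly at learning rate 0.001, β₁ 0.9, β₂ 0.999,
ε 1e-07, decay 0; categorical cross-entropy; batch size 100; a fixed
50-epoch budget with a fresh seeded permutation each epoch (no early
stopping); no data augmentation (an augmentation hook exists, off by
default). Inputs are bilinearly resized — 224×224 by default, with a
scaled-down mode (64×64 or smaller, always flagged in configuration)
used for desk-scale experiments; pixel values are scaled to [0, 1].
Balancing by sub-sampling is applied to the *training* portion of each
fold only, after splitting: balancing the test set would distort the
reported rates, and TPR/TNR absorb test imbalance. An image is
classified "effect" when that output activation is larger; exact ties
resolve to "effect", the conservative error for a welfare monitor.
Group-level classification averages post-softmax confidence vectors
over all images of an (animal, time point) group and decides from the
mean (not by majority vote).

## Evaluation

Confusion counts treat "effect" as positive; accuracy, TPR and TNR are
reported per fold and summarized as mean ± sample standard deviation
(ddof = 1; the convention is otherwise unstated). Ratios with zero
denominators — possible in leave-one-animal-out folds holding a
single-class animal — are flagged undefined and excluded from fold
means with a logged warning, never silently zeroed. Box statistics use
linear-interpolation quartiles, whiskers at the most extreme data
values within 1.5×IQR of the quartiles, and explicit outlier lists.
Detection rates are accumulated in exact rational arithmetic and
formatted only on output.

The cross-treatment design builds the full 3×3 train×test matrix;
the (typically much larger) KXN subset is first sub-sampled *by
animals* until its image count does not exceed the smaller subsets
(matching by image count via animal-level removal — whether the
original balance was by images or animals is not determinable, so this
is a recorded design choice). Diagonal cells are evaluated
subject-disjointly (2-fold animal-level cross-validation); off-diagonal
cells train one model per row on the full matched subset; cells whose
train and test treatments share animals carry a subject-overlap flag.

## Relevance propagation

The explained quantity is the target class's pre-softmax activation
(required non-negative; softmax would mix classes). Hidden dense and
convolution layers use the positive-share (z⁺) rule — each input unit
receives relevance proportional to activation × positive weight part,
normalized per output unit, biases ignored; the input layer uses the
box (z^B) rule over the declared input range [0, 1], with the range
terms restricted to valid (unpadded) pixels so no relevance leaks into
zero padding; max-downsampling routes relevance to the winning
location; rectifiers and reshapes pass it through. Propagation runs in
float64. Denominators below 1e-12 drop that unit's relevance with a
logged conservation warning. On bias-free networks every layer's
relevance sum equals the explained score (tested to 1e-4 relative;
biases absorb relevance, so for biased networks the deviation is
reported, not asserted), all relevances are non-negative for
non-negative activations, and on small networks the propagated map
equals a literal loop-wise evaluation of the redistribution formula.
Heatmaps normalize relevance by its maximum and render a red scale,
alone, alpha-blended over the image, or as a three-panel
original/overlay/heatmap figure. For explained models whose target
activation is negative the tool refuses rather than approximates.

## Study conditions and problem sizes

The end-to-end experiments run at desk scale, chosen once:

* **Recognition study:** 40 animals × 2 time points (baseline,
  30 min) × 10 images, margin 1.0, rendered and trained at 64×64,
  50 epochs, subject-disjoint 75/25 animal split. The permuted-label
  control shuffles *training* labels at (animal, time)-group level and
  uses 20–25 epochs — a model trained on label noise stays at chance
  on held-out animals regardless of additional epochs. Chance bounds
  for the control are computed from the binomial interval at the
  number of independent test units, i.e. (animal, time) groups — the
  ~10 images of a group share one latent state and are not
  independent.
* **Averaging repeats:** ten subject-disjoint repeats; repeats after
  the first use the scaled-down 32×32 / 12-epoch setting, since each
  repeat compares averaged vs per-image accuracy *within itself* and
  the contrast does not require full convergence.
* **Cross-treatment:** 16 animals per treatment (24 for KXN before
  matching) × 2 time points × 8 images; disjoint unit signatures
  (IN: orbital tightening; KXN: ear position with slight whisker
  change; C: nose + cheek bulge); 48×48 inputs, 25 epochs.
* **Detection:** detectors trained on 40 synthetic cage scenes plus
  occluded negatives; evaluated on 200 fresh scenes of which 15% have
  the lower face occluded.

## Known limitations

* The renderer is low-dimensional; classifiers can reach ceiling
  accuracy on it. Margins, noise and identity nuisance keep the
  *relative* comparisons (subject-disjoint vs leaked, per-image vs
  averaged, within- vs cross-treatment) informative, which is what the
  package's guarantees are about.
* The stub backbone does not model ImageNet transfer quality; the
  transfer path's accuracy on real data is untested here.
* The boosted detector is deliberately small-scale (a single boosted
  stage, no attentional cascade) and is not a production Viola-Jones
  implementation.
* Relevance propagation supports the package's own layer vocabulary;
  architectures with unsupported layer types are rejected rather than
  approximated.
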