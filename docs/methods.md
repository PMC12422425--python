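# Methods

## Data model and splitting

A dataset is a manifest: ordered image records with a family label,
optional species/genus metadata (never used for prediction — the classifier
contract receives pixels only), an optional bounding box, and a split tag.
Bounding boxes use 0-based, half-open coordinates `[x_min, x_max) x
[y_min, y_max)`, so width and height are plain differences; the serialized
form is four comma-separated integers in one CSV column. Manifests are
inspectable without pixels: a record pointing at a missing file fails when
its image is loaded, not when the manifest is parsed.

The stratified split assigns, per family with `n` images,
`floor(0.6 n)` to training and halves the remainder with the odd image
going to the test set. This floor/floor/remainder rule is the unique simple
rounding rule consistent with every row of the published split table,
including all odd-remainder families, and it reproduces the table's totals
(17558 / 5856 / 5861) exactly. The published grand total is quoted in prose
as 29,374, while both published tables sum to 29,275; the tables are
treated as ground truth and the prose figure is not "corrected". Which
images land in which split is decided by a per-family seeded shuffle:
counts are a pure function of family totals, membership is a function of
the seed.

## Preprocessing and the augmentation policy

Images are resized (bilinear, anti-aliased, anisotropic — aspect ratio is
not preserved and no padding is added, since only the target size is
specified) and z-score normalized per channel with the canonical ImageNet
statistics, means (0.485, 0.456, 0.406) and stds (0.229, 0.224, 0.225).

The augmentation policy is an ordered schedule of 11 techniques in four
groups: Basic (horizontal flip, 90° rotation; p = 1.0), Color (jitter,
channel shuffle, Gaussian noise, median blur, sharpness; p = 0.1 each),
Geometric (thin plate spline, 2×2 crop, random erasing; p = 0.1 each) and
Mix (CutMix; p = 0.1). Each technique fires independently per pass. Two
readings of the Basic group's p = 1.0 are possible; the default treats it
as "the op is always invoked with its internal parameter random" (flip
coin 0.5, rotation angle uniform over {0°, 90°, 180°, 270°}), because
applying a fixed flip+rotation to every pass would contribute nothing to
the pass-to-pass variability the ensemble exists to measure. The
alternative fixed-transform reading is available via
`default_policy(basic_randomized=False)`.

Magnitudes the source schedule leaves unstated are conservative and
config-exposed: color jitter strength ±0.1 on brightness/contrast/
saturation, Gaussian noise σ ∈ [0.01, 0.05] on the [0, 1] scale, median
blur 3×3, unsharp-mask amount ∈ [0.5, 1.5], thin-plate-spline displacement
of a 4×4 control grid by ≤ 5% of the image size, erasing 2–10% of the
area with uniform noise, CutMix patch 10–40% of the area. "Crop (2×2)" is
read literally as choosing one of the four half-size quadrants of a 2×2
grid and resizing it back. CutMix at test time draws its donor from the
same evaluation set (labels are irrelevant because the reduction uses only
per-pass arg-max labels); `apply_mix_at_test=False` restricts Mix to
training. All techniques preserve shape and channel count, and a fixed
generator state reproduces output bytes exactly.

## Classifier and training recipe

`ReferenceNet` is a deliberately small convolutional network — three 3×3
convolution blocks (8, 16, 32 channels) with ReLU, dropout and 2×2 max
pooling, global average pooling, and a linear softmax head — about 6,500
parameters at K = 15. It exists so the full pipeline (training, TTA+TTD
inference, evaluation) runs end to end on one CPU in minutes; it is not
meant to compete with large pretrained backbones, which plug in through
the same two-method contract (`n_classes`, `predict_proba`).

Dropout (rate 0.3) is attached to every weighted layer: after each
convolution's activation and on the input of the linear head. The head's
mask is placed on its input rather than on the logits so the softmax is
never computed over zeroed logits; the count of dropout layers still
equals the count of weighted layers (4). The same inverted-dropout masks
used in training are sampled at test time when `dropout=True`, making
repeated forward passes Monte Carlo draws.

Training: cross-entropy with label smoothing 0.1, AdamW (weight decay
0.01), base learning rate 0.001 modulated by cosine annealing with warm
restarts (initial period 10 epochs, period multiplier 2 — the restart
parameters are not specified by the recipe and are config-exposed),
best-checkpoint selection by minimum validation loss, early stopping with
patience 10 (patience likewise unstated; configurable). Validation loss is
computed with dropout off and no augmentation. Given one seed, training is
bit-reproducible (pure numpy, no backend nondeterminism).

## Monte Carlo confidence

`mc_predict` runs T passes (default 100): fresh augmentation draw, fresh
dropout mask, arg-max label; the final label is the mode and the
confidence the agreement fraction. Pass rng states spawn from the call
seed by counter; batch prediction derives each record's seed from
(seed, record_id), so a record's result is independent of which other
records are evaluated alongside it. Tie-breaking between equally frequent
classes — the mode definition is otherwise silent — prefers the tied class
with the largest summed per-pass probability, falling back to the smallest
class index, and is reported via `tie_broken`. The label-agreement
definition of confidence is canonical here; the mean of per-pass
probability vectors is retained only as a diagnostic (`keep_probs`).
Disabling dropout isolates the TTA-only (aleatoric) component; an empty
policy isolates the TTD-only (epistemic) component.

Confidence is bounded below by `ceil(T/K)/T` and equals 1 under unanimity;
both facts are property-tested, and the mode/confidence reduction is
verified exhaustively against enumeration for T ≤ 8, K ≤ 3.

## Evaluation

Confusion matrices count true family (rows) against predicted family
(columns). OA is the diagonal fraction as a percentage. Kappa uses the
multiclass marginal-product chance agreement, which reduces algebraically
to the binary TP/TN/FP/FN formula on 2×2 matrices (verified by exhaustive
sweep); the multiclass form is required because the published per-model
kappa values are only consistent with it. The degenerate case pe = 1
(all mass in one diagonal cell) is defined as κ = 1.

The cropped-vs-uncropped aggregator averages per-model metrics across
conditions. Relative improvement is defined as the mean of per-model
relative increases, not the relative increase of the means: the two differ
in the second decimal, and only the former reproduces the published 5.58%
figure. Display rounding is 2 decimals for percentages and 4 for kappa;
full precision is kept internally.

Per-family confidence summaries restrict to correctly classified records
(families with zero correct predictions are reported as missing, not as
zero). Paired summaries split families at a median-confidence gain of 6
percentage points into large/small improvement groups, each ordered by
descending gain. Whether "mean confidence" in a whole-test-set report
should average over all records or only correct ones is ambiguous in the
source material; the package defaults to all records for report-level
means and correct-only for the per-family summaries, and exposes both.

The taxonomic-level rule maps confidence ≥ 0.85 to a family-level call and
< 0.50 to an order-level call; the 0.50–0.85 band has no prescribed action
and is labeled "indeterminate" for expert review rather than guessing.

## Synthetic data generator

The generator renders "virtual insects" — a body ellipse with two wing
ellipses, optional legs and bristle speckles — onto uniform or cluttered
backgrounds, tracking the exact specimen mask so stored bounding boxes are
tight by construction. Each family is a prototype vector (hue, body
aspect, wing size/angle, bristle density, leg toggle, saturation, value);
specimens jitter around their prototype and are scaled so the specimen
mask covers an area fraction drawn from the requested range (the body is
sized at 55% of the target specimen area, calibrated so the realized mask
fraction matches the request in expectation). `family_similarity` shrinks
all prototypes toward their mean: 0 gives well-separated families (hues
spaced 1/K apart; a nearest-prototype classifier on rendered parameters is
exact), 1 makes them coincide, and classifier confusion grows monotonically
in between.

This emulates the statistical structure that drives the study design —
class imbalance (an `imbalanced_counts` profile with one ~4× rarer
family), small specimen-to-image area fractions, background clutter,
expert-tight boxes, controllable inter-class similarity — and deliberately
nothing else. It contains no photographic texture, no pose articulation,
no occlusion, and its class signal is partly chromatic; passing tests
demonstrate that the pipeline's machinery is correct and that the crop
effect has the expected direction under controlled conditions, not that
any particular accuracy transfers to photographs of real flies.

## Problem sizes and numerical choices

The crop-effect experiment uses 6 families × 200 images (128×128,
cluttered, specimen area fraction 0.02–0.3), 64×64 network inputs, 10
epochs and 3 training seeds with a majority rule on the cropped ≥
uncropped comparison; these sizes make the paired contrast decisive (the
observed gap is tens of accuracy points) while keeping a full run in the
minutes range on one CPU. Probabilities are clamped at 1e-12 inside
logarithms; resize always returns floats in [0, 1]; augmented images are
clipped to [0, 1] after every color operation. Stochastic tests use fixed
seeds and tolerances of four binomial standard errors.

## Known limitations

- The reference network is intentionally tiny; absolute accuracies on real
  photographs are out of scope, and no pretrained backbone adapters ship.
- The generator's families are separable largely by color and shape
  statistics, which is easier than real inter-family morphology.
- CutMix at test time assumes an evaluation set of at least two images
  when `apply_mix_at_test` is enabled.
- No temperature scaling, deep ensembles or variational alternatives are
  provided; the confidence estimate is exactly the pass-agreement
  statistic.
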