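# flyconf

Uncertainty-quantified, family-level classification of fly (Diptera)
pollinator images.

Automated pollinator monitoring needs more than a label: downstream
ecological decisions (abundance counts, conservation assessments) require
knowing *how sure* the classifier is, especially for fly families whose
morphology differs only in subtle cues like wing venation or bristle
placement. `flyconf` implements a complete pipeline for this problem:
stratified dataset handling with expert bounding boxes, a stochastic
test-time augmentation (TTA) policy, Monte Carlo dropout (test-time
dropout, TTD), an agreement-based confidence estimator, and an evaluation
layer that quantifies how bounding-box cropping changes accuracy and
confidence. A procedural generator of labeled "virtual insect" images makes
the whole pipeline testable without downloading a single photograph.

## The method

For an input image $x$, run $T$ stochastic forward passes (default
$T = 100$). Each pass $t$ draws a fresh random augmentation $\tilde{x}$ of
the image and a fresh dropout mask (rate 0.3, active at test time) in the
network $f_{\theta^{(t)}}$, and takes the arg-max label:

$$y^{(t)} = \arg\max_k\, f_{\theta^{(t)}}(\tilde{x}), \qquad t = 1,\dots,T$$

The final prediction is the mode of the pass labels,
$\hat{y} = \mathrm{mode}(\{y^{(1)},\dots,y^{(T)}\})$, and the confidence is
the agreement fraction

$$\mathrm{conf}(\hat{y}) = \frac{1}{T}\sum_{t=1}^{T}\mathbb{I}\,[y^{(t)} = \hat{y}].$$

TTA perturbs the input, probing aleatoric (data) uncertainty; TTD samples
subnetworks, probing epistemic (model) uncertainty. Evaluation uses overall
accuracy $\mathrm{OA} = \mathrm{tr}(C)/N$ on the confusion matrix $C$ and
Cohen's kappa $\kappa = (p_o - p_e)/(1 - p_e)$ with the multiclass chance
agreement $p_e = \sum_k r_k c_k / N^2$. A confidence-based reporting rule
maps each prediction to a taxonomic rank: confidence ≥ 0.85 → report the
family; < 0.50 → back off to order (Diptera); in between → flag for expert
review.

## Worked example

```bash
flyconf synth --families 6 --per-family 50 --size 128 --area 0.02:0.3 \
        --background cluttered --seed 7 --out data
flyconf split data/manifest.csv --seed 7 --out data/split.csv
flyconf train data/split.csv --input-size 64 --epochs 10 --no-augment \
        --seed 0 --out ckpt
flyconf predict data/split.csv --ckpt ckpt/checkpoint.npz \
        --mc-iterations 100 --seed 0 --out preds.csv
flyconf evaluate preds.csv data/split.csv --out report
```

The same experiment through the library, contrasting cropped and uncropped
training on a cluttered synthetic fixture where specimens can occupy as
little as 2% of the frame:

```python
import flyconf as fc

spec = fc.SyntheticSpec(n_families=6, images_per_family=200, image_size=128,
                        specimen_area_fraction_range=(0.02, 0.3),
                        background="cluttered", seed=7)
uncropped, cropped = fc.crop_effect_fixture(spec, split_seed=7)
pp = fc.PreprocessSpec(target_size=(64, 64))
for name, manifest in [("uncropped", uncropped), ("cropped", cropped)]:
    net = fc.ReferenceNet(n_classes=6, input_size=64, seed=0)
    fc.train_classifier(manifest, net, fc.TrainConfig(max_epochs=10, seed=0),
                        preprocess_spec=pp)
    print(name, round(100 * fc.evaluate_accuracy(net, manifest, "test", pp), 1))
```

prints

```
uncropped 48.3
cropped 95.4
```

— training on images cropped to the specimen's tight bounding box nearly
doubles held-out accuracy when the insect is small against a cluttered
background, the central effect the evaluation layer is designed to measure.
(The accuracies are seed-reproducible; different seeds move them a few
points without changing the direction.)

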