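# wildcount

Detection and counting of animals in aerial census photographs, built on
rotation-invariant Fourier HOG descriptors and a boosted per-pixel
classifier, with the evaluation statistics used to compare automated
counts against manual ones and a synthetic scene generator with exact
ground truth.

The intended users are ecologists and survey teams who photograph a
sampling strip from a light aircraft and need per-image animal counts
without weeks of manual enumeration, and anyone studying rotation-invariant
descriptors on overhead imagery.

## The method

In an overhead photograph an animal can point in any direction, so the
descriptor fed to the classifier must be rotation invariant by
construction. The image gradient at each pixel, written as a complex
number `r e^{iθ}`, defines a Dirac delta on the circle of orientations;
its Fourier coefficients are `F_m = r e^{imθ}`. Convolving each
coefficient plane with circular harmonic kernels
`U_{j,k}(ρ, ψ) = w_j(ρ) e^{ikψ}` (Gaussian rings indexed by `j`,
wavenumber `k`) yields raw features `X_{k,m} = U_{j,k} * F_m` which
transform under an image rotation by `α` as

    X'_{k,m} = e^{iα(m−k)} X_{k,m}

Features with `m = k`, and products `X_{k1,m1} X_{k2,m2}` with
`m1 − k1 + m2 − k2 = 0`, are therefore exactly invariant; their real and
imaginary parts form the descriptor. A pixel-wise AdaBoost classifier
(depth-2 trees) is trained on descriptors of annotated animal centres
versus background; at detection time every pixel above a local-contrast
threshold is classified, 8-connected positive pixels are grouped, and
each group is counted as one animal.

Per-image counts are compared with reference counts via totals, means,
coefficient of variation, RMS error `sqrt(1/N Σ D_i²)` and mean signed
error `1/N Σ D_i`; detections are matched to true centroids within a
radius to obtain precision and recall; and the under-count fraction
`1 − automated/true` is regressed on image light level (mean HSV value)
to quantify the dim-image failure mode.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Train on five synthetic scenes and count a held-out one:

```python
import numpy as np
from dataclasses import replace
from wildcount import FeatureConfig, FourierHOG, SceneConfig, generate_scene
from wildcount.detector import DetectorConfig, detect, harvest_training_set, train
from wildcount.evaluate import match_detections, precision_recall

hog = FourierHOG(FeatureConfig())
scene = SceneConfig()                      # 256x256 px, 20 animals

images, truths = [], []
for i in range(5):
    image, truth = generate_scene(replace(scene, seed=i))
    images.append(image)
    truths.append(truth[["x", "y"]].to_numpy())
samples = harvest_training_set(images, truths, hog,
                               n_negative_per_image=20,
                               rng=np.random.default_rng(0))
classifier = train(samples, feature_config=hog.config,
                   config=DetectorConfig(seed=0))

image, truth = generate_scene(replace(scene, seed=100))
result = detect(image, classifier, DetectorConfig(seed=0), extractor=hog)
c = match_detections([(d.x, d.y) for d in result.components],
                     truth[["x", "y"]].to_numpy(), radius=12)
precision, recall = precision_recall(c)
print(f"planted animals : {len(truth)}")
print(f"detected count  : {result.count}")
print(f"TP/FP/FN        : {c.tp}/{c.fp}/{c.fn}")
print(f"precision       : {precision:.2f}")
print(f"recall          : {recall:.2f}")
```

Output:

```
planted animals : 20
detected count  : 20
TP/FP/FN        : 20/0/0
precision       : 1.00
recall          : 1.00
```

All 20 planted animals were recovered as exactly one connected component
each, with no background false positives; on larger held-out batches the
detector typically holds precision and recall above 0.9 at full light and
under-counts as the light level drops.

The same pipeline is available from the shell:

```sh
wildcount synth  --config run.cfg --n-scenes 10 --out scenes/ --seed 1
wildcount train  --images scenes/ --annotations scenes/annotations.csv \
                 --config run.cfg --out model.joblib --seed 1
wildcount detect --images scenes/ --model model.joblib --out detections.csv
wildcount count  --detections detections.csv --out counts.csv
wildcount evaluate --counts counts.csv --out report.json
```

`wildcount evaluate` accepts any per-image count table with `image_id`
and `final_manual` columns (plus `first_manual`, `second_manual`,
`automated`, `automated_<n>`), so a real survey's count file can be
evaluated directly.

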