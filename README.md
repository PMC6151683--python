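# retino-entropy

Local-entropy preprocessing of colour fundus photographs for automated
detection of referable diabetic retinopathy (DR), with the full experimental
harness around it: a grade-aware synthetic fundus generator, class balancing
by lossless rotate/flip augmentation, a small convolutional network, and the
paired statistics needed to compare two input representations on the same
test images.

The package is for people studying image preprocessing for retinal
screening: it lets you ask, on data you control, whether feeding a CNN the
*entropy image* of a photograph — rather than the photograph itself —
changes detection performance, and whether that change is statistically
real.

## The method

DR severity is graded 0–4 on the International Clinical DR scale; grades 2–4
("referable DR") warrant specialist referral and form the binary target.
Lesions — microaneurysms, hemorrhages, exudates — raise the local intensity
diversity of the retina, while healthy retina is comparatively flat. The
local entropy image makes this explicit. For each pixel, over the n×n window
of the luminance image centred on it,

    E_local = − Σ_i P(i) · log2 P(i)

where P(i) is the relative frequency of gray level i within the window.
Flat regions give E ≈ 0; maximally mixed 8-bit windows approach
log2 256 = 8 bits. Entropy is computed at native resolution, then the map
is scaled to [0, 1] and downsized to the standard 100×100 network input
(originals are scaled by 1/255 and downsized the same way).

The classifier is a four-block CNN: 5×5 kernels with 32/64/64/128 filters,
2×2 max-pooling after the first three blocks, ReLU and dropout per block,
then a 256-unit fully connected layer and a 2-logit softmax head. Training
records held-out accuracy after every iteration and keeps the best-iteration
snapshot (first index on ties).

Two runs on the same test images form a paired design. The report compares
them with a Pearson chi-square test on accuracy, McNemar's test on the
discordant pairs within the truth-positive stratum (sensitivity) and the
truth-negative stratum (specificity), and DeLong's paired test on the AUC
difference.

## Worked example

```python
from retino_entropy import (SceneParams, generate_fundus, to_luminance,
                            local_entropy, EntropyConfig, transform_fundus,
                            ConfusionCounts, metrics)

img, grade, log = generate_fundus(SceneParams(grade=4, seed=7, image_size=256))
ent = local_entropy(to_luminance(img), EntropyConfig(block_n=9))
std = transform_fundus(img, EntropyConfig(block_n=9))
print(f"grade {grade} scene: {log.lesion_count()} lesion primitives")
print(f"entropy image: min {ent.min():.3f}, max {ent.max():.3f} bits")
print(f"network input: shape {std.shape}, range [{std.min():.3f}, {std.max():.3f}]")

m = metrics(ConfusionCounts(tp=1099, tn=1484, fp=96, fn=321))
print(f"accuracy {100*m['accuracy']:.2f}%, sensitivity {100*m['sensitivity']:.2f}%, "
      f"specificity {100*m['specificity']:.2f}%")
```

prints

```
grade 4 scene: 87 lesion primitives
entropy image: min 0.000, max 4.761 bits
network input: shape (100, 100, 1), range [0.000, 0.580]
accuracy 86.10%, sensitivity 77.39%, specificity 93.92%
```

The grade-4 scene draws 64 microaneurysms, 8 hemorrhages, 9 exudates and 6
extra tortuous vessel segments on top of the disc and vessel tree; its
entropy image peaks at 4.76 bits where lesion, vessel and retina gray
levels mix. The confusion counts illustrate the performance metrics:
2,583 correct calls of 3,000 is exactly 86.10% accuracy.

The full experiment — generate a graded synthetic dataset, balance the DR
grades, split, train one model per representation, and emit the paired
report — is one call:

```python
from retino_entropy import ExperimentConfig, run_comparison
report, provenance = run_comparison(ExperimentConfig(seed=17))
print(report.to_frame())
```

or, from the shell, `retino-entropy compare-experiment --seed 17 --out run/`.
A CLI also exposes the individual stages (`synth`, `transform`, `build`,
`evaluate`); label files use the `image,level` CSV dialect throughout, so a
directory of real screening photographs with such a label file drives the
same pipeline unchanged.

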