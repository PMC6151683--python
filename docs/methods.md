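# Methods

## The entropy-image representation

The package's central transform replaces each pixel of an 8-bit luminance
image with the Shannon entropy (base 2) of the gray-level histogram over the
n×n window centred on that pixel. Several details of this filter are not
fixed by the idea itself; the package resolves them as follows.

**Sliding window, not tiles.** The filter is per-pixel: every pixel gets the
entropy of its own window. A tiled variant would change the output
resolution and couple the result to tile phase.

**Boundary handling.** Symmetric (mirror) padding. Zero padding would
inject an artificial gray level at the border and inflate border entropy;
mirroring keeps border statistics close to the interior's. Windows larger
than the image are legal — padding extends as far as needed.

**Histogram bins.** 256, one per 8-bit gray level; P(i) is a relative
frequency over gray levels, so the natural bin count is the code size of
the input. The output is therefore bounded by log2 256 = 8 bits, and the
[0, 1] standardization divides by that bound. `bins` is configurable for
inputs quantized differently.

**Even window sizes.** For even n there is no centre pixel; the window
covers offsets [−n/2, n/2−1] in each axis. This is a documented convention,
only n = 2 among the studied sizes is affected, and the brute-force oracle
in the test suite encodes the same convention independently.

**Luminance.** ITU-R BT.601 luma, round(0.299 R + 0.587 G + 0.114 B),
rounded to integers so the histogram remains over 8-bit levels.

**Order of operations.** Entropy is computed at the native resolution of
the photograph and the entropy map is downsized afterwards (bilinear,
anti-aliased). Computing entropy after downsizing is available as an
ablation flag (`entropy_after_resize`) but is off by default: downsizing
first destroys the fine lesion texture the filter is meant to pick up.

**Implementation.** One summed-area table per gray level present in the
image gives all window counts in O(L·H·W); the identity
E = log2 N − (1/N) Σ c_i log2 c_i avoids materialising per-window
histograms. The test suite proves equality (< 1e-9) with an explicit
per-window histogram oracle for n ∈ {2, 3, 5, 9, 11}, plus permutation
invariance over gray-level relabelings and equivariance under the dihedral
symmetries for odd n.

## Synthetic fundus scenes

The generator exists so the whole pipeline — transform, balancing, split,
training, paired statistics — runs and is testable without any external
image set. A scene is a circular field of view on a near-black background
with a radial brightness falloff and fine multiplicative texture, a bright
off-centre optic disc, and a branching vessel tree grown as wiggly random
walks from the disc. DR grade g controls lesion content:

| lesion | count | photometry |
|---|---|---|
| microaneurysm | 4·g² | small dark red dots (radius ≈ 0.6–1% of image) |
| hemorrhage | 2·g, grades ≥ 2 only | larger dark blobs (≈ 2–3%) |
| exudate | 3·max(0, g−1) | bright yellow-shifted blobs (≈ 1–2%) |
| neovessels | 6 extra tortuous segments, grade 4 only | thin dark paths |

Grade 0 draws no lesion primitive. Per-camera jitter multiplies brightness
and contrast by independent factors in ±10%, emulating unstandardised
multi-clinic acquisition. Every image is deterministic given its seed
(per-image seeds are `dataset_seed XOR index`), and each image carries a
JSON scene log of drawn primitives so tests can assert content without
image analysis.

What the generator does *not* emulate: real lesion morphology and colour
distributions, media opacity and focus problems, laser scars, camera optics,
or inter-grader label noise. Passing the desk-scale comparison therefore
shows that the pipeline is correct and that the entropy representation
preserves enough lesion signal for learning — it does not certify
performance on real screening photographs. The structural property the
method requires — referable-grade scenes have higher mean local entropy
(n = 9) than grade-0 scenes on average — is asserted empirically over
multiple seeds.

## Dataset balancing and splitting

Minority DR grades are expanded to per-grade targets using the 8 dihedral
symmetries of the square raster (identity, three rotations, two flips, two
flip-rotations) — the only augmentations that are lossless on a square
grid; non-square inputs are centre-cropped first. Every source contributes
its identity variant; extra variants are dealt round-robin over a seeded
shuffle of the sources walking a fixed op cycle, so per-source load differs
by at most one ("increased evenly") and no (source, op) pair repeats.
Feasibility bound: a target may not exceed 8× the source count.

The split samples per grade, without replacement, from a seeded generator.
Default mode is leakage-safe: all variants of one source photograph land on
the same side, with group-granularity overshoot discarded rather than moved
to the test side. `leakage_safe=False` reproduces the augment-then-split
order used by screening pipelines that balance classes before splitting;
the screening-scale arithmetic targets (30,000/3,000 with test counts
1,500/375/375/375/375) are checked in that mode, since that is the order
that produces them.

## The network and its training

Architecture (fixed by contract, audited in tests): four convolutional
blocks, all 5×5 kernels, filters 32/64/64/128, 2×2 max-pool after blocks
1–3 only, ReLU and a dropout layer in every block, flatten → 256-unit fully
connected → dropout → 2-logit softmax head. Convolutions are unpadded, so
the spatial path is 100 → 96 → 48 → 44 → 22 → 18 → 9 → 5 and the flatten
width is 3,200; total trainable parameters are 1,179,458 for 1-channel
input and 1,181,058 for 3-channel, verified against the closed-form sum of
k²·c_in·c_out + c_out terms.

Entropy inputs are single-channel; original photographs three-channel.

The implementation runs directly on numpy in float32. The first
convolution is lowered to an im2col patch matrix and one GEMM; the deeper
convolutions use a per-tap accumulation (one (N, c_in) @ (c_in, c_out) GEMM
per kernel offset), which avoids materialising the 25-fold patch matrix
where channel counts make the GEMM efficient anyway. The first layer skips
its input gradient. Pooling routes gradients to the per-window argmax
(first on ties); dropout is inverted (identity at evaluation). The
optimizer is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Gradients were
verified against central finite differences layer-wise and end-to-end.

Training choices the architecture leaves open, with the package defaults:

* **iterations** — 200 by default, read as epochs; a `batch` unit is
  available since the term is ambiguous in common usage.
* **learning rate** — 1e-3 (TrainConfig); the desk-scale experiment uses
  3e-4, which is stabler at its small step counts.
* **batch size** — 64; desk scale uses 16 so an epoch contains enough
  optimizer steps to make progress.
* **dropout rates** — 0.25 per conv block and 0.5 in the head by default.
  At desk scale these prevent learning outright: with only ~10² optimizer
  steps the regularisation noise dominates the weak gradient signal, and
  training collapses to the majority class (measured; memorization of 40
  random-noise images succeeds without dropout and fails with it). The
  desk-scale experiment therefore sets both rates to 0. The layers remain
  in the network; the rates are per-run configuration, logged in every
  provenance archive.

Model selection follows a best-of-K rule: held-out accuracy is recorded
after every iteration and the parameter snapshot of the best iteration
(first on ties) is kept. When the held-out set is the test set this leaks
test information into selection; the experiment harness replicates that
protocol deliberately (it is the protocol being studied), and the training
API accepts any evaluation set, so a separate validation split is a
caller-side choice.

## Paired evaluation

Accuracy, sensitivity and specificity come from exact confusion counts at
the fixed call threshold 0.5 (a score equal to the threshold is called
positive). Degenerate denominators yield `None` rather than an exception.
AUC uses the Mann–Whitney midrank formulation (ties count ½), proven equal
to the pairwise brute force in tests.

For two methods on the same images:

* **accuracy** — Pearson chi-square, 1 df, no continuity correction, on the
  2×2 correct/incorrect × method table; a warning is attached when an
  expected cell drops below 1.
* **sensitivity / specificity** — McNemar's test on discordant pairs within
  the truth-positive / truth-negative stratum. Discordance b + c > 25 uses
  the continuity-corrected statistic (|b−c|−1)²/(b+c) on 1 df; otherwise
  the exact two-sided binomial (cross-checked against statsmodels). Zero
  discordance returns p = 1 with a note. The corrected statistic is kept in
  its textbook form even at b = c, where it is conservative relative to the
  exact test; the branch-agreement test therefore samples |b−c| ≥ 2.
* **AUC difference** — DeLong's paired structural-components test
  (midranks), verified to 7 digits against pROC's `roc.test` and tracked
  against a paired sign-flip permutation oracle; a seeded paired bootstrap
  (2,000 resamples) is available as an alternative.

Type-I error of all four tests is checked empirically: with two identical
stochastic classifiers, each rejects at ≈ 5% over 200 simulated replicates.

## Desk-scale experiment sizes

The default `ExperimentConfig` generates 160/30/30/30/30 images per grade
at 192×192, expands each DR grade to 60 by augmentation, and splits
120/40/40/40/40 train and 40/15/15/15/15 test (280 train / 100 test,
referable prevalence 0.43 in test), training 15 iterations with batch 16.
These sizes were chosen so the full two-representation comparison finishes
in under ten minutes on one CPU while every stage — generation, transform,
balancing, leakage-safe split, training, best-of-K selection, paired
statistics — runs at realistic proportions. All counts are configuration
values; full-scale runs are the same code pointed at larger numbers or at a
directory of real photographs with an `image,level` label file.

## Known limitations

* The synthetic task is much easier than real referable-DR screening; both
  representations reach high-90s accuracy at desk scale, so the experiment
  demonstrates pipeline correctness, not the clinical superiority of either
  representation.
* The numpy network is single-device and sized for 100×100 inputs; it is
  not a general deep-learning framework.
* Quality grading of photographs is consumed as a boolean flag
  (`interpretable`), never computed: the upstream exclusion it models is a
  manual, subjective step.
* JPEG sources are accepted on input, but all generated artifacts are
  written as lossless PNG so that round trips stay bit-exact.
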