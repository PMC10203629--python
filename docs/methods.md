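# Methods

## The model

LightMixer is a lightweight convolutional classifier for tomato-leaf
disease images (ten classes: nine diseases plus healthy). The network is

    stem → DCWP → LR → head

* **Stem.** A channelwise (grouped, groups = channels) 3×3 convolution
  with stride 3, padding 1 and bias. For RGB input this is 9·3 + 3 = 30
  trainable values and maps 224×224 → 75×75. The decoding is forced by
  the published per-layer count: a dense 3→3 convolution would carry 84
  parameters, only the channelwise variant gives 30.
* **DCWP ("depth convolution with Phish").** Pointwise 1×1 expansion
  3→C (C = 224 by default; 896 parameters), depthwise 3×3 over C
  channels with "same" padding and no bias (9·C = 2 016), Phish, a dense
  2×2 fusion convolution C→C with no padding (4·C² + C = 200 928,
  shrinking 75→74), and batch normalization (2·C = 448). The source
  table prints the depthwise row with 0 parameters, which no trainable
  convolution satisfies; this implementation makes it a trainable
  bias-free depthwise 3×3 and excludes that row from exact-count checks.
  The 2×2 kernel of the fusion layer is itself a decoding: 200 928 =
  4·224² + 224 admits only kernel 2×2 with bias, and the 75→74 shape
  change forces stride 1 with no padding.
* **LR ("light residual").** Depthwise 9×9 over C channels ("same"
  padding, bias; 81·C + C = 18 368 — the 9×9 kernel is again forced by
  the printed count), Phish, batchnorm, pointwise 1×1 C→C (C² + C =
  50 400), Phish, batchnorm; an identity skip adds the block input to
  the final batchnorm output, with no projection and no activation after
  the addition. The body can be repeated in series (`lr_repeats`), each
  repeat with its own skip; the default is one repeat, matching the
  published layer table. (The published total of 1.577 M parameters
  exceeds the single-instance sum of the table's rows, 276 232; the
  discrepancy is surfaced, not resolved — no repeat count reproduces it
  exactly either.)
* **Head.** Global average pool → flatten → dropout → affine C→K. The
  affine map carries C·K + K parameters (2 250 for 224→10). The network
  returns raw scores; softmax is applied in the loss and at prediction.

The activation throughout is **Phish**,

    Phish(x) = x · tanh(GELU(x)),
    GELU(x)  = 0.5·x·(1 + tanh(√(2/π)·(x + 0.044715·x³)))  (tanh form),

smooth, nonnegative, ≈ x for large positive x and → 0 for large negative
x. Constants are held in double precision; arrays are evaluated in their
native dtype.

## Numerical engine

No automatic-differentiation framework is used: `lightmixer.nn` is a
small float32 engine with hand-derived backward passes. Dense
convolutions are lowered to BLAS matrix products via `as_strided` im2col
patches; depthwise convolutions (the only grouped case the architecture
uses, and the only one supported — other group counts raise
`NotImplementedError`) use shifted-slice accumulation over kernel
offsets, which also yields a stride-general transposed pass for the
gradient. Batch normalization uses eps 1e-5 and running-statistics
momentum 0.1 (unbiased variance in the running buffer, biased in the
batch pass, the usual convention). Dropout is inverted (scaling at train
time). Cross-entropy is computed through a shifted log-sum-exp. The
engine is verified in the test-suite against scipy 2-D correlation
(forward) and float64 central differences through the entire assembled
network (backward).

Weight initialization is Kaiming fan-in normal (std = √(2/fan_in)) for
convolutions and the affine head, zero biases, batchnorm scale 1 / shift
0, all drawn from a generator seeded by `ModelConfig.seed`; two
assemblies from the same config are bit-identical.

## Parameter and MAC accounting

Every constructed layer carries a declarative `LayerSpec` with a
closed-form count (conv: (k_h·k_w·C_in/groups)·C_out + bias; batchnorm:
2·C; linear: in·out + out). The table total must equal the runtime
enumeration of trainable arrays — the two routes are independent and the
suite holds them equal for all four ablation variants. MACs count
convolution and linear multiplies only (output positions · k_h · k_w ·
C_in/groups · C_out); bias, normalization, activations and pooling are
excluded, and "FLOPs" is reported as 2·MACs. At 224×224 the default
model measures 1.488 GMACs; published FLOPs figures for this family of
models use unstated conventions, so no exact cross-check is claimed.

Ablation variants: base (stem + head), +DCWP, +LR, both. When DCWP is
off but LR on, a pointwise 1×1 expansion adapter (3→C) is inserted so
the LR block sees its configured width; its parameters are included in
reported totals. This is the minimal wiring that keeps the variant
well-typed; the original ablation's wiring is unpublished.

## Synthetic data

The real study data is the PlantVillage tomato subset — 18 835 images,
ten classes, roughly 5:1 imbalanced (largest class 5 357, smallest
1 000). The synthetic generator emulates its *structure* at desk scale:
by default, per-class counts are the real counts divided by 50 and
rounded (43, 20, 32, 38, 20, 35, 34, 28, 20, 107 — 377 images), rendered
at 64×64 RGB. Each class recipe draws a textured leaf-green background
(HSV hue band, low-resolution noise upsampled bilinearly), superimposes
soft-edged lesion disks with class-specific colour, count and radius
(many small dark dots for bacterial spot, few large patches for late
blight, none for healthy, …), and adds Gaussian pixel noise (sd 8).
Each class also occupies its own background hue band, reflecting the
whole-leaf colour shifts (chlorosis, necrosis, mold cover) that real
foliar disease produces; these bands are what makes the classes
certifiably separable by a shallow baseline at this image budget — with
a single shared green band, lesion morphology alone left a
one-hidden-layer classifier near 60% here.

What the generator does **not** emulate: real leaf shape and venation,
lighting and pose variation, background clutter, intra-class phenotype
diversity, or inter-class visual similarity structure. Passing tests on
the synthetic data therefore certify the pipeline (shapes, accounting,
optimization, metrics) and that the model can extract colour/morphology
signal — they say nothing quantitative about accuracy on real
PlantVillage images.

## Splitting and augmentation

The 80/10/10 split is stratified per class (the real data's imbalance
makes unstratified 10% splits noisy): per class, indices are shuffled
under the split seed and apportioned by largest remainder, ties broken
in favour of train, then val, then test. A class of 7 yields (5, 1, 1);
a class of 100 yields exactly (80, 10, 10); the three parts always
partition the input.

Training-time augmentation follows the study's named transforms with
standard magnitudes (the study prints none): random resized crop with
area scale (0.7, 1.0) and aspect ratio (3/4, 4/3), horizontal and
vertical flips at p = 0.5, rotation uniform in ±30°, then bilinear
resize to 224×224. The pipeline is seeded and deterministic; with crop
scale and ratio pinned to 1, flips at p = 0 and rotation 0 it reduces
exactly to the plain resize.

## Training

Defaults follow the study recipe: Adam (betas 0.9/0.999, eps 1e-8),
learning rate 1e-4, cross-entropy, 70 epochs, batch size 32 (the batch
dimension printed in the published layer table; the hyperparameter table
omits it). No schedule, no weight decay, no early stopping. The
checkpoint of the best-validation-accuracy epoch is retained and
restored after the final epoch. All run randomness (shuffling, dropout,
augmentation) derives from `TrainConfig.seed`.

**Desk-scale recipe.** The full-scale schedule is ~33 000 Adam steps
(70 epochs × ~470 batches). A 10-epoch run on the 377-image synthetic
default is ~100 steps, where the full-schedule rate of 1e-4 cannot move
the weights far enough (it reaches ~0.74 validation accuracy at epoch
10, and 0.90 only around epoch 23). Short runs therefore use Adam's
conventional default rate 1e-3, exposed as
`training.desk_scale_train_config()`; with it the default model exceeds
90% validation accuracy within 10 epochs on one CPU. `TrainConfig`'s
own defaults remain the study values.

## Metrics

Confusion matrices put true classes on rows, predictions on columns.
Per-class one-vs-rest counts give recall TP/(TP+FN), precision
TP/(TP+FP), F1 2TP/(2TP+FP+FN), and a one-vs-rest accuracy
(TP+TN)/total; headline accuracy is trace/total. Aggregates are macro
(unweighted class means) — the study's single printed precision/recall
values differ from its accuracy, which rules out micro averaging.
Undefined ratios (zero support or zero predictions) are reported as 0
with a warning, never NaN. The row-normalized matrix divides each row
by its support, so diagonals are per-class recall; zero-support rows are
emitted as zeros and flagged.

## Problem sizes

Unit tests run narrow variants (6–16 channels, 15–32 px inputs) for
speed; the architecture-accounting and desk-scale training checks run
the full 224-channel model (accounting at 224×224 input, training at the
generator's native 64×64). The acceptance script regenerates the
synthetic dataset, retrains the default model for 10 epochs and
re-derives every reported number at run time.

## Known limitations

* The published parameter totals (1.577 M in the ablation table,
  0.013 M for the stem+head base) are inconsistent with any decoding of
  the published per-layer table (276 232 and 2 280 + adapter-free
  respectively); this package reproduces the per-layer counts exactly
  and reports the discrepancy rather than reverse-engineering a
  different architecture.
* Single-stream modules: a layer caches one forward pass, so the engine
  supports plain loops, not branched reuse of one module instance.
* CPU-only float32; no mixed precision, no distributed training, no
  learning-rate schedules.
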