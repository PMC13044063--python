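# Methods

This note records the modelling assumptions, conventions and open design
choices behind the package, in the order the pipeline runs.

## Segmentation

Images are real-valued in [0, 1] (8-bit files are divided by 255 on read).
Grayscale conversion uses the Rec.601 luma weights (0.299, 0.587, 0.114), the
standard convention in image-processing libraries. Binarisation is a fixed
global threshold, default 0.3: scenes of bright produce on black cloth have a
bimodal grey-level histogram with a trough well below the bulb intensity, so
a fixed cut is adequate and cheap; adaptive (e.g. Otsu) thresholding is
deliberately out of scope. Pixels exactly at the threshold count as
foreground (half-open convention — this makes the boundary case testable).
Connected components use 8-connectivity; only the largest component is kept,
so multi-bulb frames reduce to the dominant bulb. The "contour" is the
longest sub-pixel marching-squares boundary of that component. Bounding boxes
are 0-based, half-open, row-major.

Whether the classifier should consume the masked full frame or the tight
crop of the bulb is genuinely open. Both paths exist
(`datapipe.segment_dataset`, modes `"mask"` and `"crop"`). The desk-scale
demonstration trains on full frames: with the short five-epoch schedule the
scale variance introduced by per-image crops slows optimisation enough that
training does not converge, while full frames (the bulb is always centred
and of similar scale in this imaging setup) train reliably.

## Network architecture

The backbone is the ResNet34 layout: a 7×7 stride-2 convolution (3→64) and a
3×3 stride-2 max-pool take a 224×224×3 input to 56×56×64; four stages of
basic residual blocks with the (3, 4, 6, 3) plan at (64, 128, 256, 512)
channels follow (the first block of stages 2–4 downsamples with stride 2 and
a 1×1 projection shortcut); global average pooling and a linear layer
produce the logits. Stage widths and depths are configurable for desk-scale
work, but the (3, 4, 6, 3) plan is the reference configuration.

Four toggles define the model family:

* **Depthwise substitution.** The *second* 3×3 convolution of every basic
  block — in all 16 blocks, projection blocks included — becomes a 3×3
  depthwise convolution. This is the only substitution point consistent with
  the joint parameter/compute totals below: per block it saves exactly
  `9C² − 9C` parameters and `(9C² − 9C)·H·W` MACs.
* **SE attention**, placed after the second batch norm, before the residual
  summation, in every block. The gating MLP is `C → ⌊C/r⌋ → C` with `r = 16`
  (the original SE default; at least one hidden unit), ReLU inside
  (configurable) and sigmoid gates. SE is *excluded* from the two profiling
  variants, which isolate the depthwise effect.
* **SiLU activations** everywhere (stem, blocks, block outputs). Note
  `SiLU(0) = 0·σ(0) = 0`; its derivative is `σ(x) + x·σ(x)(1−σ(x))`,
  continuous everywhere.
* **Nested residual.** The inner skip is a *parameter-free* identity added
  around the first conv–BN–activation sub-unit, active only when that
  sub-unit preserves shape (stride 1, equal channels); projection blocks omit
  it. Any parameterised inner branch would change the published parameter
  totals, so the parameter-free reading is the only consistent one; the
  toggle provably changes no count (asserted in tests).

Convolutions carry no bias (each is followed by batch norm, which contributes
the 2C affine parameters). Initialisation: Kaiming fan-out normal for conv
weights, uniform ±1/√n for the head, BN γ=1/β=0 — except the last BN of every
residual branch, whose γ starts at 0 so each block begins as (a gated)
identity. This residual-friendly init materially speeds up short schedules.

## Parameter and MAC accounting

Per layer: a standard K×K convolution counts `K²·C_in·C_out` weights and
`K²·C_in·C_out·H_out·W_out` multiply–accumulates (output spatial size); a
depthwise convolution `K²·C_in` and `K²·C_in·H_out·W_out`; batch norm 2C
parameters and no MACs; the linear head `in·out + out` parameters and
`in·out` MACs; the SE MLPs their weight+bias parameters and `2·C·⌊C/r⌋` MACs.
Pooling, activations and elementwise additions contribute zero MACs — the
common profiler convention. The two-decimal "GFLOPs" figure is the MAC total
divided by 1e9; lightweight-CNN tables conventionally use the word GFLOPs
for this quantity.

Under these conventions, at 224×224 with a 1000-way head:

* baseline: 21,797,672 parameters (21.8 M), 3,663,761,408 MACs (3.66 G);
* depthwise variant: 10,514,408 parameters (10.5 M), 1,826,491,904 MACs.

The exact depthwise MAC total is 1.8265 G, which rounds to 1.83 G; published
comparisons of this architecture pair print 1.82 G, consistent with rounding
the ≈1.84 G savings before subtracting. The package always reports the value
it computed. A hook-based instrumented count over a real forward pass must
equal the closed form exactly for every variant; the acceptance script
refuses to report otherwise.

Wall-clock latency (`measure_latency`) is reported for information only; it
depends on BLAS, hardware and implementation maturity of depthwise kernels,
and no ordering between variants is asserted.

## Data pipeline

Augmentation is a deterministic offline ×3 expansion: each original
contributes itself, one Gaussian-noise copy (σ = 0.02 in [0,1] units,
clipped) and one rotated copy (uniform in ±30°, same canvas, black padding —
consistent with the black-cloth background). Per-class counts therefore
scale exactly by the factor (95 → 285, 96 → 288, 296 → 888).

The 6:2:2 split assigns `round(0.6n)` to training and halves the remainder
between validation and test by largest remainder, the odd item going to the
test set. (Published per-row splits of this arithmetic are not internally
consistent under any single tie rule — one row resolves the odd item toward
test, another toward validation — so one deterministic rule is fixed and
only the self-consistent rows are asserted: 285 → (171, 57, 57) and
888 → train 533.) Splits are stratified per class. By default augmented
copies of one original stay within one partition (augment after splitting)
to avoid leakage; augmenting before splitting is also supported, which is
what reproduces the published row arithmetic exactly. Five-fold partitioning
is stratified with fold sizes differing by at most one.

## Training and evaluation

The training protocol is plain minibatch SGD on softmax cross-entropy:
224×224 inputs, batch size 8, base learning rate 0.01, 30 epochs, momentum
0.9, no weight decay, no schedule, no early stopping. Cross-entropy is the
loss (softmax classification; consistent with loss magnitudes in the 0.08–0.9
range that this protocol produces). The checkpoint with the best validation
accuracy is returned. Batch-norm running statistics update with momentum 0.3
by default — higher than the usual 0.1 so that eval-mode statistics track the
batch statistics within a handful of epochs; for long schedules the
converged statistics are essentially unchanged.

Evaluation builds a K×K confusion matrix (rows = actual, columns =
predicted). For class k: TP is the diagonal entry, FN the rest of row k, FP
the rest of column k, TN everything else. Accuracy is trace/total; per-class
precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F1 their harmonic mean; macro
scores are unweighted class means (three-class summary rows are treated as
macro averages). A zero denominator defines the metric as 0 with a warning.

## Synthetic fixtures

The generator emulates the imaging setup — one garlic bulb per frame against
near-black cloth — not garlic photometry. A bulb is a jittered ellipse
(centre ±4 % of frame, radii 22–34 % of frame) with warm off-white colour,
clove-ridge texture (sinusoidal angular modulation) and mild Gaussian pixel
noise; the background is near-black but non-zero (≤ 0.05) so the 0.3
threshold is genuinely exercised. Damage is an elliptical patch that
perturbs both colour and intensity: a dark reddish-brown bruise on the bulb
body for local damage, a blue-grey decay patch anchored at the bulb base for
root damage (patch radii 28–55 % of the bulb radii). The two damage classes
therefore differ in both location and channel statistics, which is what
makes a small CNN learn them within a five-epoch desk-scale budget. Every
image is fully determined by its seed; ground-truth bulb and damage
geometry is returned for scoring segmentation and attention maps.

What passing tests on these fixtures shows — and does not show: they verify
the mechanics end to end (segmentation geometry, optimisation, metric
arithmetic, attention plumbing) on a separable, controlled population. They
do not certify performance on real garlic, where damage is subtler,
illumination varies and class boundaries are ambiguous; the published
headline accuracies on the authors' captured dataset are not reproducible
without that dataset and are not claimed here.

## Desk-scale training configuration

The in-repo demonstration trains the full classifier at reduced width:
stage channels (8, 16, 32, 64), 64×64 inputs, 60 images per class (36 test),
the train partition augmented ×3, five epochs, batch 8, lr 0.01. Under these
conditions best validation accuracy reaches ≥ 0.95 (1.00/0.97/0.97 over
three training seeds in pre-freeze pilots) in well under a minute on one
CPU core.

## Grad-CAM

The hook point is the output of the last residual block (the final
convolutional stage; 512×7×7 at full width and 224 input). Channel weights
are the spatial means of the target-logit gradients at that layer; the map
is the ReLU of the weighted channel sum, bilinearly upsampled to the input
size and min–max normalised to [0, 1] (an identically-zero map is returned
as zeros with a warning). Overlays blend a blue→red colouring at α = 0.5.
Normalisation makes the map invariant to positive rescaling of the target
logit.

On the synthetic fixtures, localisation quality is class-asymmetric: maps
for root damage concentrate tightly on the decay patch (up to 24/24 test
images with the top-5 % mass centroid inside the ground-truth box), while
maps for local damage vary with the training seed, because the synthetic
classes are separable from global colour statistics and a GAP-head network
is never forced to attend locally. The localisation property test therefore
asserts a conservative pilot-derived floor — centroid-in-box on at least one
third of damage images, evaluated at 224 px where the final-stage grid is
7×7 — against a ≈10 % chance rate. Sharper localisation is an attribute of
harder, texture-defined damage, not of this generator.

## Numerical notes

All tensors are float64; gradients of every layer are verified against
central finite differences at 1e-6 step. The sigmoid is computed in the
numerically stable split form. Cross-entropy uses the log-sum-exp shift.
SE hidden widths floor at one unit. Max-pool padding uses −∞ so padded
positions can never win the argmax. Degenerate inputs raise typed errors:
empty foreground (`SegmentationError`), empty datasets, class-count
mismatches, non-finite training loss.

## Known limitations

* Pure-NumPy compute: full-width training at 224 px is possible but slow;
  the package is built for inspectability and desk-scale verification, not
  GPU throughput.
* Single-object scenes: only the largest foreground component is analysed.
* The alternative attention modules and exotic activations beyond the
  implemented set are interface stubs by design (the activation registry
  covers ReLU/ReLU6/ELU/LeakyReLU/Mish/GELU/sigmoid/hard-sigmoid/hard-swish/
  SiLU; only SE attention is implemented natively).
* No pretrained weights and no transfer learning; all training is from
  random init.
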