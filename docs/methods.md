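# Methods

This note records the models and procedures leaffuse implements, the
parameter choices that matter, and the design decisions taken where the
problem left the design open.

## Problem setting

Micronutrient deficiencies (boron, iron, manganese, zinc) in crops such
as banana show first as visible leaf symptoms — chlorosis (yellowing) and
necrosis — that overlap heavily across nutrients. The toolkit addresses
two tasks: *classification* (which deficiency, from an RGB leaf image)
via lightweight transfer-learning ensembles, and *severity quantification*
(how bad, on the same image) via colour analysis. All components run at
desk scale on synthetic data with known ground truth.

## Data pipeline

Images are 8-bit RGB, stored dir-per-class, resized to 224×224 (bilinear
by default; nearest-neighbour is selectable because it is exact on
size-preserving calls, which pixel-identity tests need) and rescaled by
1/255 at model input.

Class balance is restored by augmentation *planning*: each class below
the per-class target contributes `target − original` augmented copies, so
a six-class set with target 1000 always totals 6000 images afterwards.
Augmentation draws are multiplicative brightness (range [0.8, 0.8] by
default) followed by clipping to [0, 255], central crop-and-resize zoom
(range [0.5, 0.5]), rotation up to ±20° with nearest-border fill, and
horizontal flip with probability ½. Brightness clipping, the zoom
reading (crop-and-resize), and the rotation bound are package choices;
only the ranges themselves are externally specified. Every draw is
determined by the pair (config seed, draw seed).

The stratified 80/20 split assigns `floor(0.8·n + 0.5)` samples per class
to training; the remainder goes to validation. Augmentation is planned on
the full set but applied to the training partition only, so validation
images are never synthetic derivatives of training images.

## Synthetic data

The leaf generator renders an ellipse (default semi-axes 90×60 px on a
224 canvas) in leaf green (40, 120, 40) on a near-black background
(10, 10, 10), then places yellow (180, 170, 40) discs of random radius at
random interior positions until the symptomatic area reaches the target
fraction within ±0.02 of the leaf area (the final disc is shaved
pixel-wise if it would overshoot). Gaussian pixel noise (σ = 3 by
default) is added last. The colours are chosen so the HSV yellow band
separates cleanly from both lamina and background, giving the severity
pipeline an exact oracle. What this generator does *not* emulate —
venation, specular highlights, soil/background clutter, overlapping
leaves, illumination gradients — bounds what passing tests show: they
validate the algorithmic chain, not field robustness.

The member-output generator draws, per sample and member, a predicted
class that equals the true class with probability equal to the member's
target accuracy (otherwise a uniformly random wrong class), then a
Dirichlet row peaked at that class (concentration 20 by default); if the
draw's argmax lands elsewhere the two coordinates are swapped, so
member accuracy is Binomial(n, accuracy) by construction and converges at
the usual √n rate (tested at n = 5000, tolerance 0.03).

## Mutated head

The head is global average pooling (when the backbone emits a feature
map) followed by Dense(256, relu) → Dense(256, relu) → Dropout(0.5) →
Dense(K, softmax). Hidden activations are rectified-linear by convention
(only the output activation is externally fixed); both are configurable.
Its trainable parameter count is closed-form:
`(d·256+256) + (256·256+256) + (256·K+K)` — 337,412 at d = 1056, 394,756
at d = 1280 (K = 4), 732,168 for the two-head ensemble.

Training uses mini-batch Adagrad (base lr 0.01857, accumulator
initialized at 0.1, batch 16) on categorical cross-entropy, inverted
dropout, and a 30-epoch cap. Early stopping: an epoch improves when
validation accuracy *strictly* exceeds the best so far; after 5
consecutive non-improving epochs training stops and the best-epoch
weights are restored (a run whose validation accuracy saturates in epoch
1 therefore stops at epoch 6). Learning-rate-on-plateau: factor 0.5 after
3 stagnant epochs, floored at 1e-5. The plateau parameters and the
strict-improvement convention are package choices.

The `FeatureExtractor` protocol decouples the head from any framework;
the bundled `RandomProjectionExtractor` (8×8 block-mean downsample, fixed
random projection) is a deterministic stand-in that runs the full
training path in seconds. No pretrained-backbone loader is bundled; real
backbones plug in through the same protocol.

## Ensemble fusion

All member outputs are points on the K-simplex, and every fusion rule is
a convex combination, so fused outputs stay on the simplex — the central
invariant, asserted over 10⁴ random outputs.

The attention matrix maps the concatenated member outputs (length N·K)
to N logits: W ∈ R^{N×NK}, α = softmax(W·concat). A per-class-row
alternative (K×NK) would make the softmax length K, inconsistent with α
being a per-model weight vector summing to 1 over models; the per-model
shape is used. Zero W reproduces uniform attention and hence exact
average fusion; uniform scalar weights do the same (equivalence asserted
to 1e-12).

W is trained by Adagrad on cross-entropy with the analytic gradient
(softmax Jacobian composed with the convex-combination derivative);
probabilities are floored at 1e-12 before logs. When all members emit
identical outputs the gradient vanishes identically, so uniform attention
is a stationary point and training is a no-op — a useful symmetry test.
Argmax ties anywhere in the package break toward the lowest class index.

## Fusion-weight search

Search space: w1 ∈ [0, 1] continuous (w2 = 1 − w1), learning rate from
{0.018750, 0.01750, 0.002}; ten trials of ten epochs by default; each
trial's seed is derived by stable hashing of (master seed, trial index).
Only the fusion layer is (re)trained per trial; member heads are fixed.
Failed trials are recorded and excluded from the best; ties break to the
earliest trial.

The `surrogate` strategy fits a Gaussian process (RBF + white kernel,
normalized targets) per learning rate on the observed (w1, accuracy)
pairs and proposes the expected-improvement maximizer over a 101-point
w1 grid, falling back to random draws while history holds fewer than
three successful trials or a learning rate is unexplored. The `grid`
strategy enumerates the product grid in a fixed coarse-to-fine order
(endpoints, then interval midpoints at doubling resolution, learning
rates cycling within each w1), so any trial budget spans the whole
interval while an exhaustive budget still visits every point exactly
once.

## Severity quantification

Segmentation is a classical, fully deterministic pipeline chosen
deliberately over a learned segmenter: excess-green index 2G − R − B,
Otsu threshold, morphological opening (disc radius 2), largest connected
component. A frame with no separable foreground returns an empty mask
with a flag, never an exception.

Symptom pixels are those inside the leaf mask whose HSV colour falls in
the yellow band — hue 40–70° (0–360° scale), saturation ≥ 0.25,
value ≥ 0.25 by default; the band is configurable since "yellow" ranges
vary by camera. DoS is the symptomatic fraction of leaf area; it is NaN
(flagged) when the leaf mask is empty.

Channel trimming interprets the coverage probability as the fraction of
*leaf-masked* channel values inside a window centred at the channel mean
(rounded half-up): the window starts at [X, X] and grows one intensity
unit per side per iteration, clamped to [0, 255], until coverage ≥ 0.9.
Coverage is monotone non-decreasing and the window is bounded, so the
loop always terminates; on a uniform 0–255 channel the final half-width
is 115 (coverage 231/256 ≈ 0.902). The GCV is the mean of in-window
values. Whether trimming should use whole-image or leaf-only pixels was
open; leaf-only is used because background pixels say nothing about leaf
health.

GI = G/(R+G+B+1e−6) on the unit-normalized GCVs is bounded by 1, so
fixed thresholds of 0.95/1.05 cannot fire on the raw value; the package
therefore applies them to gi_ratio = GI / reference-GI, where the
reference comes from a user-supplied healthy leaf image or a configured
constant. Without a reference the ratio and its label are reported as
unknown and flagged. The three-band DoS labels (mild < 0.10 ≤ moderate
< 0.30 ≤ severe) are package defaults, configurable, and not calibrated
against chlorophyll-meter readings.

One consequence of 90%-coverage trimming worth knowing: a symptomatic
area below roughly 10% of the leaf is *discarded by design* during
trimming, so raw GI ties with the healthy value (up to pixel noise,
~1e-5) until the symptom fraction exceeds the trim allowance, and then
decreases. The monotonicity test therefore allows ties at 1e-3 while
asserting a genuine overall decrease.

## Metrics

Per class, one-vs-rest on the K×K confusion matrix: accuracy
(TP+TN)/n·100, precision TP/(TP+FP)·100, recall TP/(TP+FN) (unit scale,
with a percent echo), F1 as the harmonic mean of unit-scale precision and
recall, scaled to percent at report time. All rates are computed on
[0, 1] internally and scaled only when reported, which keeps the F1
formula consistent regardless of the scale the inputs are displayed in.
Zero-denominator metrics report 0 with an explicit `undefined` flag so
reports are total functions. Overall accuracy is trace(cm)/n·100; macro
averages are unweighted class means. Support-weighted (micro) recall
equals overall accuracy on a square matrix — asserted as an identity
test.

## Problem sizes and determinism

Test and acceptance runs use fixture sizes chosen for statistical
resolution at interactive speed: 2000-row member tables (binomial
standard error ≈ 0.01 on an accuracy), 5000 rows for law-of-large-numbers
checks (tolerance 0.03 ≈ 3 standard errors), 224-canvas leaves
(~17,000 leaf pixels), 10-trial searches, and 20 seeded leaves per
symptom level for DoS recovery. Every random draw in the package flows
from an explicit seed; repeated runs are bit-identical.

## Known limitations

- Synthetic leaves are geometric idealizations; field performance of the
  severity pipeline on real imagery is untested here.
- The severity thresholds interact with the reference-leaf choice; a
  poorly lit reference shifts all GI ratios.
- The surrogate search assumes a smooth accuracy surface in w1; a highly
  multimodal objective would favour the grid strategy.
- The attention fusion operates on member *outputs* only; feature-level
  fusion is out of scope.
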