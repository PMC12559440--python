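# leaffuse

A toolkit for diagnosing crop nutrient deficiency from leaf images, built
for plant-phenotyping and agricultural computer-vision work. It covers the
three stages of a lightweight mobile-CNN diagnosis pipeline — a "mutated"
transfer-learning classification head, attention-weighted ensemble fusion
of member classifiers with a sequential search over fusion weights and
learning rate, and greenness-index severity quantification — and ships a
synthetic-data module (leaves with known symptom masks, classifier outputs
with known accuracy) so every stage is testable at desk scale without any
image downloads.

## The methods

**Mutated head.** A frozen pre-trained backbone (e.g. NASNetMobile,
feature dimension 1056, or MobileNetV2, 1280) is topped with

```
GlobalAveragePooling → Dense(256, relu) → Dense(256, relu)
→ Dropout(0.5) → Dense(K, softmax)
```

trained with categorical cross-entropy and Adagrad (base learning rate
0.01857, batch 16, ≤ 30 epochs, early stopping at patience 5,
learning-rate reduction on plateau). The head's trainable budget is exact:
`(d·256+256) + (256·256+256) + (256·K+K)`, giving 337,412 parameters for
d = 1056 and 394,756 for d = 1280 at K = 4 (732,168 for the two-model
ensemble).

**Ensemble fusion.** Member classifiers emit probability vectors
O₁..O_N ∈ [0,1]^K. Three fusion rules are provided:

- *average*: Ô = (1/N) Σ Oᵢ;
- *global*: Ô = Σ wᵢ·Oᵢ with fixed w on the N-simplex (w₁ + w₂ = 1 for
  two members);
- *attention*: α = softmax(W·concat(O₁..O_N)) with trainable
  W ∈ R^{N×NK}, Ô = Σ αᵢ·Oᵢ, trained by cross-entropy with Adagrad, so
  the better member is emphasized per input.

**Fusion-weight search.** A tuner maximizes validation accuracy over
w₁ ∈ [0,1] and a categorical learning rate {0.018750, 0.01750, 0.002},
ten trials by default. Strategies: `random`, `grid` (coarse-to-fine
enumeration), and `surrogate` — sequential model-based optimization with a
Gaussian-process regressor per learning rate and an expected-improvement
acquisition over a 101-point w₁ grid.

**Severity scoring.** For one leaf image: segment the leaf (excess-green
index 2G−R−B, Otsu threshold, morphological opening, largest component);
detect chlorotic pixels in the HSV yellow band; report the Degree of
Severity DoS = symptomatic area / leaf area. Per RGB channel, an intensity
window centred at the channel mean grows one unit per side until it covers
≥ 90% of leaf pixels; the trimmed channel means (GCVs) give the Greenness
Index GI = G/(R+G+B+1e−6). Severity thresholds (above 1.05 high, below
0.95 minor) apply to the ratio of GI to a healthy-reference GI.

## Worked example

```python
import numpy as np
from leaffuse import (SyntheticLeafSpec, gen_leaf, score_image, gen_member_probs,
                      fuse_table, fused_accuracy, SearchSpace, run_search,
                      fusion_objective)

# severity of a leaf with a 30% planted chlorotic area
healthy = gen_leaf(SyntheticLeafSpec(symptom_fraction=0.0, seed=2))
sick = gen_leaf(SyntheticLeafSpec(symptom_fraction=0.30, seed=1))
report = score_image(sick.image, reference_img=healthy.image)
print(f"DoS      = {report.dos:.3f}  ({report.dos_label})")
print(f"raw GI   = {report.gi:.3f}")
print(f"GI ratio = {report.gi_ratio:.3f}  ({report.label})")

# fuse a strong (95%) and a weak (25%) member; search the fusion weight
rng = np.random.default_rng(0)
labels = rng.integers(0, 4, 2000)
table = gen_member_probs(labels, [0.95, 0.25], K=4, seed=0)
print(f"average fusion accuracy = {fused_accuracy(table, fuse_table(table, 'average')):.3f}")

def objective(params):
    return fusion_objective(table, params, mode="global", seed=0)

res = run_search(objective, SearchSpace(), n_trials=10, strategy="surrogate", seed=0)
w1, lr = res.best.params
print(f"searched weights = ({w1:.3f}, {1-w1:.3f}), lr = {lr}")
print(f"searched fusion accuracy = {res.best.val_accuracy:.3f}")
```

prints

```
DoS      = 0.288  (moderate)
raw GI   = 0.541
GI ratio = 0.901  (minor)
average fusion accuracy = 0.594
searched weights = (0.677, 0.323), lr = 0.0175
searched fusion accuracy = 0.943
```

The severity pipeline recovers the planted 30% symptom fraction to within
two points; the chlorotic leaf's greenness sits at 90% of the healthy
reference, below the 0.95 threshold. Plain averaging of a 95%-accurate
and a chance-level member lands near 59% accuracy, while the searched
weighting leans on the strong member and recovers 94%.

A command-line interface wraps the same functionality:

```
leaffuse synth --classes 4 --n 20 --out data/
leaffuse train --data data/ --feature-dim 64 --out model/
leaffuse search --probs members.csv --trials 10 --strategy surrogate --out search/
leaffuse severity --image leaf.png --reference healthy.png --out report.json
leaffuse evaluate --model model/ --data data/ --out report/
```

Every run writes a `manifest.json` (config echo, seeds, versions) beside
its outputs.

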