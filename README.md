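# sonomil

Weakly supervised, patient-level classification of thyroid-style ultrasound
image bags with dual-attention multiple-instance learning (MIL).

## The problem

A patient's ultrasound exam yields a variable number of 2D images, but the
diagnostic ground truth (histopathology) exists only at the patient level:
malignant if *any* nodule was confirmed malignant.  Annotating individual
images is expensive and often impossible retrospectively.  MIL fits this
setting exactly: each patient is a *bag* `B_i = {x_ij}` of image *instances*
with one label `y_i ∈ {0,1}`, and a positive bag is assumed to contain at
least one positive instance.

`sonomil` is for researchers building or benchmarking weakly supervised
ultrasound classifiers: it implements the dual-attention bag classifier,
its Meanpool/Maxpool MIL baselines, the training and patient-level
cross-validation protocol, evaluation metrics, attention-based instance
ranking — and a synthetic speckle-image cohort generator with instance-level
ground truth, so the whole pipeline is testable without clinical data.

## The model

Each image is encoded by a convolutional backbone into a feature map
`h_ij = f_θ(x_ij) ∈ R^{C×H×W}`.  A **spatial attention** block refines each
map with non-local attention over a 0.5× downsampled key/value copy,

    Ψ12 = softmax( ψ1(h_ij)ᵀ ψ2(h̃_ij) / τ ),    h'_ij = ψ4(Ψ12 · ψ3(h̃_ij)) + h_ij,

then global average pooling gives instance vectors `v_ij ∈ R^C`, and a
**gated instance attention** block scores and aggregates them,

    a_ij = w_cᵀ ( tanh(W_a v_ij) ⊙ σ(W_b v_ij) ),
    α_ij = exp(a_ij) / Σ_k exp(a_ik),            z_i = Σ_j α_ij v_ij,

with `p_i = softmax(Wᵀ z_i + b)` as the patient-level prediction, trained
with cross-entropy on bag labels only.  The baselines replace the whole
dual-attention stage with a masked mean or max over the pooled instance
vectors.  Two backbone profiles exist: `resnet34` (C=512, C′=128, τ=128,
D=256, 256×256 inputs) and a CPU-scale `tinycnn` (C=64, 64×64 inputs).
See `docs/methods.md` for every convention and default.

The network runs on a small NumPy reverse-mode autodiff engine shipped in
`sonomil.nn`; no GPU or deep-learning framework is required.

## Worked example

```python
import tempfile
from sonomil import (AttentionMILClassifier, load_manifest, load_bag_images,
                     split_patients, auroc)
from sonomil.simulate import SynthConfig, generate_cohort

# 1. synthetic cohort: 60 patients, half malignant, witness rate 0.3
work = tempfile.mkdtemp()
record = generate_cohort(SynthConfig(n_patients=60, seed=7), work)
bags = load_manifest(record.manifest_path)
for b in bags:
    load_bag_images(b, size=64)

# 2. patient-level split
split = split_patients(bags, test_frac=0.2, k=5, seed=7)
test = [b for b in bags if b.patient_id in split.test_patients]
trainval = [b for b in bags if b.patient_id not in split.test_patients]

# 3. fit the dual-attention classifier (tinycnn profile)
clf = AttentionMILClassifier(epochs=20, random_state=7).fit(trainval)
print(f"best epoch {clf.best_epoch_}, val AUROC {clf.best_val_auroc_:.3f}")

# 4. held-out evaluation and attention ranking
scores = clf.decision_function(test)
print(f"test AUROC {auroc(scores, [b.label for b in test]):.3f}")
top = clf.attention_rankings(test[:1])[0]
print(f"patient {top.patient_id}: top instance {top.order[0]}, "
      f"alpha {top.alpha[top.order[0]]:.3f}")
```

prints

```
best epoch 18, val AUROC 0.720
test AUROC 0.972
patient P0003: top instance 7, alpha 0.125
```

The validation AUROC drives model selection; the test AUROC is patient-level
discrimination on held-out patients; the ranking line shows which image of
the first test patient the instance attention weighted highest (on synthetic
bags these can be checked against the planted per-image labels in
`truth.csv`).

Command-line equivalents: `sonomil simulate`, `sonomil split`,
`sonomil train`, `sonomil evaluate`, `sonomil rank` (see `--help`).

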