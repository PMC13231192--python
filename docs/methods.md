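# Methods

## Problem and model

`sonomil` performs weakly supervised, patient-level benign/malignant
classification from bags of grayscale ultrasound images.  The unit of
supervision is the patient: bag `B_i = {x_ij}` with `n_i` images and one
binary label `y_i` (1 = malignant, defined as "any nodule malignant", i.e.
the OR over the patient's nodule diagnoses).  No image-level annotation is
used for learning — the standard multiple-instance assumption: a positive
bag contains at least one positive instance, a negative bag none.

The classifier has three stages.

1. **Backbone.**  Each image is encoded into a spatial feature map
   `h_ij = f_theta(x_ij) in R^{C x H x W}`.  Two variants share this
   contract: `resnet34` (the standard 34-layer residual network with the
   final fully connected layer removed; C = 512, total stride 32, 256x256
   inputs give 8x8 maps) and `tinycnn`, a fixed 4-block network
   (conv3x3/stride 2 without bias, BatchNorm, ReLU; channels 8-16-32-64;
   C = 64, 64x64 inputs give 4x4 maps) small enough to train from scratch
   on one CPU in minutes.  ImageNet-pretrained weights for `resnet34` can be
   loaded from a local `.npz`; nothing is downloaded and no test requires
   them.

2. **Dual attention.**
   *Spatial attention* (per instance): 1x1-convolution projections
   `psi1, psi2, psi3: C -> C'` form queries from the full-resolution map and
   keys/values from a 0.5x bilinearly downsampled copy;
   `Psi12 = row_softmax(Q K / tau)` with `Q in R^{HW x C'}`,
   `K in R^{C' x HW/4}`; the context `Psi12 V` is mapped back to C channels
   by `psi4` and added residually, so the block starts as the identity
   (`psi4` zero-initialised).
   *Instance attention* (per bag): pooled vectors `v_ij in R^C` (global
   average over H x W) are scored by the gated mechanism
   `a_ij = w_c^T (tanh(W_a v_ij) * sigmoid(W_b v_ij))`,
   `alpha_ij = softmax_j(a_ij)`, and the bag embedding is
   `z_i = sum_j alpha_ij v_ij`.

3. **Classifier.**  `p_i = softmax(W^T z_i + b) in R^2`; `p_{i,1}` is the
   malignancy score.  Training minimises mean cross-entropy
   `-(1/N) sum_i log p_{i,y_i}`.

The Meanpool/Maxpool baselines share the backbone and classifier code path
and replace the whole dual-attention stage by a masked channel-wise
mean/maximum over the pooled raw backbone vectors (both attention
sub-modules absent).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `C'` (spatial projection width) | 128 (resnet34) / 32 (tinycnn) | query/key/value channels |
| `tau` | 128 / 32 | attention logit scale; fixed constant, not `sqrt(d_k)`; the small profile scales it with `C'` so initial logit spread is comparable |
| `D` (gated hidden width) | 256 / 64 | rows of `W_a`, `W_b` |
| dropout | 0.25 | on the spatial-attention context and the gated hidden layer; inactive at evaluation |
| optimiser | SGD, momentum 0.9, weight decay 5e-4 | classical momentum; decay applied to the gradient |
| learning rate | 1e-3 | half-cosine warm-up from 1e-6 across epoch 0; x0.1 at epochs 50 and 75 |
| epochs / batch | 100 / 10 patients | batches zero-padded to the largest bag |
| augmentation | flip p=0.5, rotation in {0,90,180,270} deg | training path only; the two orders generate the same dihedral group |
| normalisation | resize, ImageNet mean/std | grayscale replicated to 3 channels; resize target 256 by default, 64 for the tinycnn profile |
| operating threshold | 0.5 | recorded in every report; optional Youden-on-validation mode |

Model selection is by validation AUROC, ties toward the earlier epoch.
A single experiment seed fans out (via SHA-256 of `(seed, name)`) into
independent substreams for splitting, weight init, dropout, augmentation
and batch shuffling, so components are individually reproducible.

## Numerical engine and choices

The network runs on a small in-repo reverse-mode autodiff engine over NumPy
(`sonomil.nn`): tensors record primitive operations (arithmetic, matmul,
reshape/slice, reductions, conv2d via windowed tensordot, max pooling) and
gradients are accumulated in reverse topological order.  Every primitive is
verified against central finite differences in the test suite; an
end-to-end attention chain passes a gradient check at 1e-3 relative
tolerance.  Further conventions:

- Spatial positions flatten row-major over (H, W); the loop-based oracle
  tests pin this.
- The 0.5x "bilinear" downsample uses the corner-excluding convention, which
  at exactly scale 0.5 equals 2x2 mean pooling; it is implemented that way
  and requires even H, W (an explicit error otherwise).
- Masked softmax adds -1e9 to padded logits; after max-shifting, their
  exponentials underflow to exactly 0, so padded attention weights are
  exactly zero and real weights sum to 1.
- Padded instance slots never enter the backbone: the forward pass gathers
  mask-selected instances into a flat batch and scatters pooled vectors
  back, so padding invariance is exact, not approximate.
- Cross-entropy clamps the true-class probability at 1e-12; the loss is
  never infinite.  Softmaxes subtract the row maximum before
  exponentiation.
- `psi4` (spatial attention output projection) and `w_c` (instance
  attention scoring vector) are zero-initialised: the spatial block starts
  as the identity and the instance attention starts uniform, so the
  dual-attention model begins at the meanpool baseline and sharpens as
  evidence accrues.  Both stabilise early training; with randomly
  initialised `w_c`, early attention can lock onto uninformative instances
  and occasionally stall a 30-epoch run.
- BatchNorm is used in both backbones.  A per-image normalisation
  (GroupNorm) was tried for `tinycnn` and removed most cross-image contrast
  from the pooled features, stalling from-scratch training at this
  protocol's fixed learning rate.  The BatchNorm here is deterministic
  given the seed, so reproducibility guarantees are unaffected.
- Ranking ties (equal attention weights) preserve original instance order;
  tie scores in AUROC get the Mann-Whitney half credit; AUPRC uses
  non-interpolated step summation.
- Parameters are float32; reproducibility checks compare losses at 1e-6,
  acknowledging float non-associativity.

## Synthetic cohorts

Clinical bags with per-image truth are not available at desk scale, so the
generator plants the signal explicitly.  Every image is a bright elliptical
"nodule" on a darker background under multiplicative Rayleigh speckle,
spatially correlated over ~1 px cells (Gaussian-smoothed multiplier, unit
mean) and clipped to [0,1].  Malignant instances additionally get (i) a
boundary radius modulated by a low-order random Fourier series (harmonics
2-5, relative amplitude 0.18 by default) — the irregular-margin cue — and
(ii) 3-8 punctate high-intensity spots (radius 1-2 px, peak 0.85-0.95,
minimum separation 4 px) — the microcalcification cue.  Nodule position,
size, orientation and echogenicity are randomised identically for both
classes, so global brightness is uninformative: a bag-level pixel-mean
classifier scores near chance (AUROC ~0.57 on a seeded 120-patient cohort),
while the planted texture/shape signal is clearly separable.

A cohort draws bag sizes uniformly from [3, 12]; a positive bag contains
exactly `max(1, round(witness_rate * n))` malignant instances (default
witness rate 0.3) placed at random; cohort prevalence defaults to 0.5 over
200 patients.  Regeneration from the same configuration is bit-identical,
including the PNG files.

What the generator does *not* emulate: acquisition physics (beamforming,
attenuation, shadowing), operator and vendor variability, anatomical
context, multiple nodules per image, or label noise from mixed benign and
malignant nodules.  Passing tests on these cohorts therefore demonstrate
that the implementation can recover a planted multiple-instance signal and
that attention localises witness instances — not clinical performance.

## Benchmark problem sizes

The standard experiment (`sonomil.benchmark.run_synthetic_benchmark`, also
run by `scripts/acceptance.py`) uses three independent replicates: fresh
200-patient cohort, patient-stratified 90/10 split, first fold of the
5-fold partition for train/validation (144/36 patients), 30 training epochs
(no milestone decay falls inside them) with the tinycnn profile, evaluation
on the 20 held-out test patients, and attention localisation pooled over
the replicates' positive test bags against the witness-rate random
baseline (one-sided binomial test).  These sizes are the package's
reference configuration for CPU-scale experimentation; the full published
protocol (resnet34, 256x256, 100 epochs, milestones 50/75) remains
available through the same configuration objects.

## Limitations

- The engine is single-threaded NumPy; resnet34-scale training is
  impractical here and is exercised only at the forward/contract level.
- AUROC/AUPRC are reported without confidence intervals (no DeLong or
  bootstrap); fold-to-fold dispersion is the only spread reported.
- The benchmark's 20-patient test sets make single-replicate AUROCs coarse
  (steps of 0.01); conclusions should rest on replicate means.
- With `witness_rate` near 1 the attention advantage over mean pooling
  shrinks by construction; the default 0.3 keeps the tasks distinct.
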