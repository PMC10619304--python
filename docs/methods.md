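# Methods

## The problem

Monitoring glioblastoma under treatment requires comparing MRI scans of the
same patient months apart.  The standard deep-learning route — segment both
scans with a model trained on a large annotated cohort, register them, and
subtract — needs training data, annotations and a registration step, each a
source of cost and error.  `longimap` implements an alternative: a generative
adversarial model trained **on the two scans of one patient only**, with no
annotations, no pretraining and no registration.

## Model

Let `t1` and `t2` be the baseline and follow-up T1 contrast-enhanced volumes
after preprocessing (shared 3D grid, intensities in [0, 1]).  Training works
on random 2D slices along the third axis.

A U-Net generator `G` receives an augmented slice `x` of `t1` and outputs an
additive change map `M = G(x)`; the synthetic follow-up slice is `x + M`.  A
convolutional critic `C` scores slices with a single unbounded scalar and is
trained with the Wasserstein objective plus gradient penalty

    L_C = E[C(x + G(x))] - E[C(y)] + λ·E[(‖∇_{x̂} C(x̂)‖₂ − 1)²]
    L_G = −E[C(x + G(x))]

where `y` is an augmented slice of `t2`, `x̂` a random convex combination of
a real and a synthetic slice, and λ = 10.  Since `G` can only *add* to its
input, matching the follow-up distribution forces `M` to encode exactly what
differs between the timepoints — in T1ce, predominantly enhancing-tumor
change, because enhancing tumor is among the brightest tissue.

Registration is replaced by augmentation: each update draws an independent
rigid pose (rotations uniform in ±15° per axis, shifts uniform in [0, 10]
voxels per axis) and additive Gaussian noise (variance uniform in [0, 0.1])
for each timepoint separately, so the critic can only compare pose-invariant
content, never voxel-to-voxel alignment.

### Training schedule

One epoch = `n` critic updates followed by one generator update.  Defaults
follow the published protocol: 1000 epochs; n = 5, boosted to 100 in the
first 25 epochs and in every 100th epoch (1-based).  Because training on
near-identical volumes gives the critic no signal and destabilizes the game,
a 10×10 square of Gaussian-filtered Gaussian noise is added to every real
follow-up slice at a fixed position — 50%, then 35%, then 65% of the image
size in both dimensions, switching after 40% and 60% of the epochs and
removed after 80%.  At each switch the generator is checkpointed; the final
ensemble is the three boundary checkpoints plus the final model.  Prediction
runs every slice of the un-augmented baseline through each member and
averages, excluding each member at the pixels of its own noise square (the
mask-free final member keeps every voxel covered).

### From map to response class

The ensemble map is ternarized (strictly above +0.15 → +1 = growth, strictly
below −0.15 → −1 = reduction, else 0), connected components of ≤ 30 voxels
are removed per sign (26-connectivity by default, configurable), the outer
10 voxels of every face are silenced (brain-edge noise), and the remainder is
summed into a signed voxel count Δ.  With baseline enhancing-tumor volume v1
(from an externally supplied segmentation), the predicted follow-up volume is
v2 = v1 + Δ, saturated at 0 — a reduction cannot exceed the tumor that exists.
The volume-only response classes are:

* response: v2 < 0.5·v1 (strict)
* progression: v2 ≥ 1.25·v1 (inclusive)
* stable disease: otherwise

These boundary semantics ("more than 50%", "25% or more", "30 or less
removed") are encoded exactly.  Component filtering precedes the border crop
so the crop cannot first split or shrink a genuine component below the size
cutoff.

## Numerics

The networks run on a small, self-contained NumPy layer library
(`longimap.nn`): float32 throughout, convolutions as einsum over strided
window views, Adam with β = (0.0, 0.9) and learning rate 1e−4 by default.
Backpropagation is hand-derived.  The gradient penalty needs the derivative
of the critic's *input gradient* with respect to the critic's *weights*
(double backprop); this is computed exactly for the piecewise-linear critic
by propagating the adjoint forward through the transposed network with the
LeakyReLU masks held constant — the same almost-everywhere result reverse-mode
autodiff yields.  All gradients, including the double-backprop path, are
verified against central finite differences in the test suite.

The critic deliberately has no batch normalization (the penalty requires
per-sample gradients; batch-coupled statistics would break them).  The
generator uses batch normalization; at prediction time the normalization
statistics are computed from the predicted slice batch itself (groups of 16
slices) rather than from the running averages — the running statistics are
accumulated under augmentation noise and rigid poses and do not transfer to
the clean, un-augmented input volume.  All randomness flows from one
`numpy.random.Generator`, making training bit-reproducible for a fixed seed
on a fixed machine; across different CPU models, BLAS kernel differences can
accumulate over an adversarial run, so a multi-seed study, not a single
training, is the unit of evaluation.

AUC is the exact tie-corrected Mann–Whitney statistic via midranks; ROC
curve points come from scikit-learn.  Connected components use
`scipy.ndimage.label`; resampling uses `scipy.ndimage.zoom` with edge
replication (a constant volume stays constant); histogram matching is a
monotone quantile mapping with 256 anchors (follow-up mapped onto baseline —
the baseline defines the patient's reference intensity frame).

One caveat on pooled metrics: per-class AUCs are rank-based and invariant
under monotone rescaling of the map, but the micro-average pools growth
scores `m` with reduction scores `−m` into one ranking and is therefore not
invariant — a property of micro-averaging, not an implementation detail.

## The phantom and the desk-scale study

The synthetic phantom emulates the intensity structure the method relies on:
an ellipsoidal brain (intensity 0.5) with a darker ventricle-like interior
(0.2) and a bright spherical lesion (0.9) on background 0, lightly smoothed,
with additive Gaussian noise (sd 0.02) and a rigid inter-scan misalignment
applied to the follow-up.  The lesion volume changes by a prescribed factor;
the follow-up radius is snapped so the *voxelized* count hits the target
(the lesion center sits off-lattice, making voxel counts nearly continuous
in the radius — a naive `r·g^(1/3)` voxelization at small radii misses the
target volume by several percent).  Ground-truth voxel counts, growth and
reduction masks and the implied response class are recorded in baseline
space before misalignment.

What the phantom does **not** emulate: MRI bias fields and artifacts,
multifocal or irregular lesions, edema/necrosis compartments, ventricle
volume fluctuations, skull-strip boundary variability.  Passing the phantom
study therefore demonstrates the machinery (adversarial change mapping,
denoising, classification) under controlled conditions, not clinical-grade
performance.

The end-to-end study runs at 64×64×16 with a proportionally scaled protocol,
chosen once so a full train/predict/analyze cycle takes about a minute on
one CPU core:

* network: 3-level U-Net, 8 base features; critic channels (8, 16, 32);
* schedule: 200 epochs, 5 critic updates per epoch, boost 20 in the first 5
  and every 100th epoch — the schedule *structure* is unchanged, its sizes
  scale with the 5× shorter training;
* augmentation: rotations keep the scale-free ±15°; shifts scale with each
  axis's extent (10 px of 256 → 4 px of 64 in plane, 1 voxel along the
  16-slice axis); the noise-variance ceiling is 0.01, because the phantom
  lesion covers tens of voxels per slice rather than the hundreds a real
  enhancing tumor covers at 256², and full-scale noise would leave the
  scaled task with far less signal per sample than the setting it stands in
  for;
* phantom: baseline lesion radius 5 voxels (≈ 526 voxels), misalignment
  1.5° per axis and (0.5, 0.5, 0.25) voxels — about 2 px / 1.5° at full
  scale, typical of scanner repositioning after brain centering;
* analysis: border margin 2 voxels (the printed 10-voxel band would cover
  the entire 16-slice axis); ternary threshold, component cutoff and class
  boundaries keep their full-scale values.

Instrumented training runs motivated two of these choices.  First, an
additive map cannot express a rigid pose change, so any misalignment
residual that augmentation cannot cover becomes an irreducible target the
critic eventually locks onto, degrading the map (the generator starts
painting edge corrections); shifts must therefore cover the inter-scan
misalignment, which the full-scale protocol satisfies and the scaled one
must preserve.  Second, at baseline radius 4 the growth shell (r 4 → 4.7) is
under one voxel thick; under pose and noise augmentation the expected map
smears below the fixed 0.15 ternary threshold, so the phantom uses a
baseline lesion large enough that the change is resolvable on the grid —
a grid-resolution constraint, not a tuning of the detector.

## Limitations

* Per-patient training is expensive by construction; the model transfers
  nothing between patients.
* The map reports *any* structural change (midline shift, ventricle change,
  resection cavities), not tumor change specifically; the border crop and
  component filter remove only part of this.
* Baseline tumor volume v1 is an external input (segmentation or phantom
  truth); the package never segments.
* The adversarial game at desk scale shows the field's usual oscillation;
  the checkpoint ensemble damps but does not eliminate it, and single-seed
  results vary — hence the multi-seed design of the study.
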