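# Methods

This note records the models, conventions and design decisions behind
the package, including the choices made where the procedure was
genuinely open, and what the synthetic validation does and does not
demonstrate.

## Synthetic phantom cohorts

**Geometry.** A brain-shaped label grid (default 32×36×32 voxels at
6 mm; any shape ≥ 16 voxels per axis) contains cortical grey, a
subcortical white-matter core, cerebellar grey/white, and a brainstem
cylinder, built from ellipsoids so the labels are exactly left-right
symmetric.  The full-resolution analogue would be a 2 mm template
grid; the desk scale keeps the compartment topology while making CPU
training cheap.

**Forward model.** Tissue values are cerebellum-relative: cortical grey
carries `1.15 + 0.008·CL` (non-specific uptake plus amyloid-specific
signal), white matter a tracer-specific non-specific coefficient
(PIB 1.40, NAV 1.30, FBB 2.20, FBP 2.35, FMM 1.80 — the F18 tracers
show much higher white-matter retention), cerebellar grey/white
0.97/1.06, brainstem 1.20.  The pattern is blurred with the scanner
PSF (Gaussian FWHM, 0–8 mm; σ = FWHM/2.3548), then every
non-cerebellar voxel is multiplied by the acquisition `bias_factor`,
then independent Gaussian voxel noise (default SD 0.01) is added.
Applying the bias after the blur and leaving the cerebellum untouched
makes the bias *exactly* multiplicative on any cerebellum-referenced
SUVR, which is what gives the recovery experiments a sharp oracle
(CF* = 1/bias).  Under nonzero PSF the tracer-specific white matter
spills into the cortical ribbon, so amyloid-negative scans of
different tracers disagree by several CL before correction even
without any injected bias.

**Trajectories.** The generating natural-history curve is a unimodal
bell, `6·exp(−((CL−40)/25)²)` CL/year — near-zero accumulation while
negative, a ~6 CL/year peak around 40 CL, slowing at high burden.
Subject trajectories integrate `dCL/dt = f(CL)` by Euler at 120 steps
per year, with per-subject lognormal rate heterogeneity (SD 0.15 in
log space).  Baselines mix an amyloid-negative mode (N(0, 4²)) with a
uniform accumulating tail (5–90 CL, 45% of subjects).

**Cohort defaults (the study conditions).** 2–3 visits per subject,
consecutive intervals drawn in 0.6–2.0 years (always inside the
0.25–3.5-year pairing window), tracer mix PIB 0.4 / FBB 0.3 / FBP 0.3,
per-tracer multiplicative biases PIB 1.0 / FBB 0.8 / FBP 1.25, two
scanners with 4 and 6 mm PSF, and a 30% chance of switching tracer at
each follow-up visit (mirroring the historical PIB→F18 transitions).
Tracer switches are what make the biases *longitudinally* identifiable:
a switch turns a constant bias ratio into an implausible jump that the
decrease and curve losses can see.

**What the phantoms do not emulate:** registration error beyond the
small augmentation warps, anatomical variability, attenuation and
reconstruction physics, partial-volume effects at realistic cortical
thickness (the phantom cortex is ~1 voxel = 6 mm thick), longitudinal
atrophy, and off-target binding patterns.  Passing recovery tests shows
the machinery is correct and self-consistent at these conditions, not
that the learned corrections transfer to real scanners.

## Standard quantification

SUVR is a continuous-mask-weighted mean ratio (target over reference);
the same code path serves the binary standard masks (cortical grey /
whole cerebellum) and the learnable masks.  The composite reference is
the cerebellum unioned with white matter blurred at 8 mm FWHM and
thresholded at 70% of its post-blur maximum (erosion away from the
grey-white boundary).  Centiloid transforms are calibrated per tracer
from idealized groups: noiseless, blur-free, bias-free renderings at
true 0 CL and 100 CL, giving `CL = slope·SUVR + intercept` with 0/100
anchors.  Calibrating at zero PSF mimics the idealized conditions of
published transforms; cohort scans acquired at 4–6 mm PSF then show
spill-in the transforms do not absorb, which is intended.

## Natural-history curve

Pairs contribute `rate = ΔCL/Δt` at `mean = (CL_T0+CL_T1)/2`.  The
curve is a lowess fit — tricube weights, local linear regression,
smoothing fraction 0.2, two robustifying iterations (the classic
definition; the iteration count and the 201-point evaluation grid are
conventions of this implementation) — computed once on
standard-quantification PIB-only pairs and frozen.  Evaluation is
linear interpolation, clamped to the endpoint values outside the
fitted support so the training loss never sees extrapolated rates.

## Correction network and training

Architecture: N conv blocks (3D conv, kernel 4, stride 4 → instance
norm → LeakyReLU 0.01), flatten, concatenate the length-5 tracer
one-hot, two blocks of (dropout → linear → batch norm → tanh), then
linear → sigmoid → ×2, so CF ∈ (0, 2).  Because stride equals kernel,
each convolution is an exact linear map on non-overlapping 4³ patches;
the whole network is numpy with hand-derived backward passes, verified
against finite differences in the test suite.  Inputs are zero-padded
to the next multiple of 4 at every stage (how a 91×109×91 grid
survives four stride-4 stages is otherwise undefined).  The full-scale
preset uses channels (16, 32, 64, 128), FC widths (128, 64) and
dropout 0.5; the desk preset uses two blocks (8, 16), FC (32, 16) and
**no dropout** — at this parameter count dropout is not needed as a
regularizer, and experimentally its gradient noise on the concatenated
one-hot drowns the per-tracer signal and drives the network into the
collapsed CF→0 optimum.

Training operates on same-subject pairs 0.25–3.5 years apart (all
ordered pairs when three or more visits qualify), with the two pair
members presented in randomized order.  Losses are computed on
corrected Centiloids (each scan's tracer transform applied to
CF·SUVR); `L_d` and `L_c` are averaged over pairs (batch-size
invariance), `L_s`/`L_i` are computed once per batch over both members
of every pair.  The gradient of the combined loss with respect to each
corrected CL is analytic (hinge and absolute-value subgradients; OLS
slope/intercept derivatives; piecewise-constant curve slope) and is
chained through the transform into the network.

Optimization: Adam at 3e-3 with batches of 128 pairs (desk defaults;
the optimizer and learning rate are not prescribed by the method).
Batch size matters more than usual here: the per-tracer signal is
carried by the minority of tracer-switching pairs and is high-variance,
and with small batches the degenerate global-shrink direction (which
satisfies the decrease and curve losses by collapsing all corrections,
at the bounded cost β·|0−1| of the slope anchor) wins the optimization
race before tracer differentiation develops.  Early stopping monitors
the held-out fold's combined loss (patience 20); among restarts, the
model with the highest validation Spearman correlation between mean CL
and rate of change is selected — at the collapsed optimum that
correlation is destroyed, so this selection rule doubles as a collapse
guard.  Subject-level five-fold splits are balanced greedily over
(baseline tracer, visit count, baseline-CL tertile) strata; no
training pair crosses into its validation fold.

Augmentation (optional, off in the recovery experiments to keep their
oracles sharp): rotations up to 5°, a smooth random deformation field
(σ = 20 voxels, magnitude 50 voxels at 2 mm scale; both scaled by the
voxel-size ratio on coarser grids so physical displacements are
preserved), and incremental Gaussian blur to a target FWHM drawn
uniformly from [scanner PSF, 8 mm], applied as √(target²−PSF²).

## Mask derivation

Voxel weights of a reference/target pair are sigmoid-transformed
logits, constrained to the brain mask.  The loss is the mean over
tracers of `1 − R²(mask SUVR, corrected SUVR)` plus
`δ·(binarity(ref) + binarity(target))` with
`binarity = Σ(0.5 − |M − 0.5|)/B` over the B brain voxels; δ starts at
5e-4 and is ×100 after 20 epochs (one epoch = `iters_per_epoch`
gradient steps, default 100 — the full-batch gradient makes
"iteration" and "data pass" coincide, so the minibatch epoch length is
kept as an explicit knob).  After every step the logits are smoothed
with a 4 mm FWHM kernel and averaged with their left-right flip.  A
3-level multiresolution schedule (×4, ×2, ×1 downsampling) with
per-level minimum iteration counts (defaults 1000/3000/8000) and a
1e-8 Pearson-improvement stopping rule completes the procedure.  The
shipped masks are thresholded at 0.5; because the optimization only
maximizes correlation, mask SUVRs are recalibrated per tracer by OLS
against the corrected SUVRs before the standard Centiloid transform is
applied.

The optimizer is momentum gradient descent normalized by the *global*
gradient RMS.  This choice is deliberate and was reached by
experiment: the per-voxel gradient magnitude is the information that
distinguishes genuinely useful voxels (on the plant-and-recover
fixture, true-mask voxels receive ~45× larger gradients than
irrelevant ones, verified against finite differences), and Adam-style
per-parameter normalization erases exactly that ratio, letting
overfitting directions win.  Two further pitfalls are handled
explicitly: initial logits are soft-clipped to [0.2, 0.8] so that
voxels outside the initial masks remain recruitable (a saturated
sigmoid freezes them), and the δ ramp is keyed to epochs rather than
raw iterations so binarity pressure does not arrive before the
correlation term has shaped the masks.

The plant-and-recover oracle uses scans whose voxel intensities are
independent lognormal fields: every voxel then carries independent
information about mask membership, which makes the hidden masks the
unique optimum rather than one point on a large equivalence class.
This is an identifiability construct, not a realistic uptake model;
with spatially-uniform compartment signals the mask SUVR is invariant
to which subset of a compartment is selected, and no optimizer could
recover exact membership.

## Evaluation conventions

* **Negative peak:** two-component 1-D Gaussian mixture by EM
  (k-means++ initialization, 10 restarts, tolerance 1e-6); the "first
  peak" is always the lower-mean component.
* **HSIC:** Gaussian kernels with median-heuristic bandwidths,
  centered-Gram V-statistic, normalized by √(HSIC(x,x)·HSIC(y,y)) so
  values lie in [0, 1] and hsic(x,x)=1.  The estimator details are a
  convention of this implementation.
* **Paired bootstrap:** groups resampled with replacement identically
  across methods (N = 10,000 by default); statistic = SD across
  groups; one-sided nonparametric p = fraction of bootstrap
  differences with sign opposite to the mean difference, reported with
  the 95% percentile CI.
* **Outliers:** consecutive-visit annual changes outside
  [−5.8, +11.2] CL/year by default.  `derive_thresholds` recomputes
  central two-sided percentile bounds at a configurable coverage
  (default 90%); the published reference range is asymmetric and its
  exact quantile construction is ambiguous between a 90th-percentile
  and a 95%-CI reading, so the printed defaults are kept and the
  recomputation rule is exposed as configuration.
* **AUC / F1 threshold:** rank AUC; the threshold maximizes F1 over
  midpoints between adjacent sorted values, ties resolving to the
  lowest cut.
* **Trajectory polynomials:** degree-5 least squares of rate on mean
  CL; the peak is the maximum over the *observed* mean-CL range (no
  extrapolated maxima), with an optional pair-resampling bootstrap CI.

## Rate-scaling simulation

20% of subjects (subject-level split) have their visit times divided
by a factor (0.9–2.0), multiplying their apparent CL/year without
touching the images.  The curve is refit and the network retrained on
the manipulated cohort; degree-5 polynomial peak-rate ratios
(scaled/unscaled subset) are then computed with the manipulated and
with the original timelines.  A faithful correction keeps the planted
ratio under the manipulated timelines and a ratio near 1 under the
original ones — the network maps single images to corrections and has
no channel through which to learn subject-level rate assignments.  At
desk scale the scaled subset contributes only ~60 pairs, so its
polynomial peak is noisy; ratios fluctuate by roughly ±20% across
seeds.

## Problem sizes

The recovery experiments use: 200 subjects (≈500 scans, ≈400 pairs) for
bias-recovery training; 400 scans on a 16³ grid for mask recovery; 150
subjects × 3 visits for the rate-scaling simulation; 500 noise-free
pairs for curve recovery.  These sizes were chosen as the smallest at
which the recovery margins are stable across seeds.

## Known limitations

* The correction learned at desk scale leaves a small global
  downscaling (~5–8% on all CFs): the slope/intercept anchors trade a
  little scale against the decrease/curve penalties, so corrected
  negative scans sit a few CL below zero.  The same trade-off is
  inherent in the loss weighting, not an implementation artifact.
* Instance normalization removes global-intensity information from the
  network input; bias identification therefore rests on spatial
  contrast and the tracer one-hot, which is sufficient for per-tracer
  biases but would not identify a purely global scanner gain from a
  single image.
* The full-scale (four-block, dropout-0.5, 2 mm) preset is provided
  but untested at scale here; all quantitative statements in this
  repository refer to the desk-scale configuration.
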