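# Methods

This note documents the models, the synthetic data, the numerical
choices, and the limits of what the tests demonstrate.

## The triage model

A patient's maximum CCTA degree-of-stenosis grade (ordinal categories
0 %, 1–24 %, 25–49 %, 50–69 %, ≥ 70 %, plus a non-diagnostic token ND)
decides the extremes: probability 0 of functional significance below
25 % DS, probability 1 at ≥ 70 % DS. Only intermediate patients
(25–69 %) are passed to the image-based classifier, and the combined
probability vector over all patients is evaluated against the reference
standard: functionally significant iff any vessel has invasive
FFR ≤ 0.80 (boundary inclusive) or high-grade (≥ 90 % DS) stenosis on
invasive angiography. ND segments are ignored whenever any diagnostic
grade exists; all-ND patients are flagged for exclusion rather than
triaged, mirroring image-quality exclusion in practice.

## Image pipeline

**Segmentation.** Every voxel is classified myocardium/background from
six 2D patches: axial, coronal and sagittal planes through the voxel at
a fine and a coarse scale (default scales 1× and 3×; coarse sampling by
linear interpolation over the widened window; mirror reflection at grid
borders, border voxel not repeated). Two identical conv + max-pool
streams (one per scale) feed a fused fully connected head. The default
patch edge is 25 voxels; the desk-scale configuration used throughout
the tests is patch edge 9, 8/16 conv channels, 3 epochs, ~1500 balanced
training voxels per volume — enough for the intensity-separable
phantoms. Inference may subsample on a stride with nearest-lattice
fill (cohort runs use stride 2; Dice is reported at stride 1).
Post-processing keeps the largest connected component; hole filling is
available but off by default because closed myocardial shells enclose
the blood-pool cavity, which 3D hole filling would annex. Automated QC
fails a mask whose volume leaves a plausible range (default 2–300 mL)
or whose largest connected component holds < 80 % of masked voxels.

**Intensity standardization.** Before patch encoding, each scan is
standardized by a piecewise-linear landmark map: the volume's 20th
percentile (background), the median over the myocardial mask, and the
99th percentile (blood pool) are mapped to −50 / 100 / 400 HU, with
linear extrapolation outside. This removes between-patient global
intensity variation (contrast timing, output calibration) while
preserving relative hypo-attenuation inside the myocardium. Without
it, patient-level intensity offsets dominate the feature space and
chance alignment of those offsets with the labels destabilizes
evaluation on small cohorts.

**Characterization.** A convolutional auto-encoder (two conv + pool
blocks, dense bottleneck, mirrored decoder with nearest upsampling)
is trained unsupervised to reconstruct in-plane patches centered on
myocardial voxels, pooled over all patients. Default patch size is
4 × 4 voxels — about one wall thickness at the phantom resolution — so
that patches are predominantly myocardial tissue wherever they sit in
the wall. Larger windows (8–16 voxels) admit large cavity/background
fractions whose between-patient variation swamps the tissue-level
signal in the pooled statistics; we measured held-out classification to
degrade from ~0.98 to ~0.7 AUC as the window grows at this resolution.
On clinical-resolution data the patch size should be scaled to the
wall thickness accordingly. Default encoding dimension is 8 (2:1
compression of the 16-pixel patch). Every masked voxel is encoded
(stride 1 by default; cohort fixtures use stride 2).

**Features.** One vector per patient: for each encoding dimension, its
mean, standard deviation, minimum, 25th/50th/75th percentiles (linear
interpolation between order statistics) and maximum over all encoded
voxels, laid out dimension-major. The summary is invariant to voxel
order and to the number of voxels.

**Classification.** RBF-kernel SVM with inverse-prevalence class
weights; features standardized with training-fold statistics; the
regularization constant chosen from {0.1, 1, 10, 100} by an inner
stratified 3-fold grid search with the one-standard-error rule
(smallest C within one SE of the best inner ROC-AUC); probabilities
from a Platt-style sigmoid fit on cross-validated decision values.
One guard departs from textbook SVM practice: if the best inner-CV
score does not exceed chance by two standard errors, the classifier
*abstains* and emits the fixed uninformative probability 0.5 for every
patient. Out-of-fold rankings produced by fitting pure-noise features
are systematically anti-predictive (we measured held-out AUC 0.38–0.46
at n = 60 with no signal), so refusing to rank is both safer clinically
and statistically honest. The abstention constant is deliberately 0.5
rather than the training prevalence: a prevalence-valued constant
re-couples predictions to fold composition and biases cross-validated
AUC downward. The guard never triggered in any measured
configuration with real lesion signal (inner AUC ≥ 0.95).

**Evaluation.** Repeated stratified k-fold cross-validation (default
10 folds, 50 repetitions, re-randomized each repetition from a
per-repetition derived seed) over the intermediate patients only; each
intermediate receives exactly one out-of-fold probability per
repetition; extremes are pinned to 0/1; AUC and threshold-0.5 metrics
are computed per repetition over all patients and aggregated as
mean ± SD. Proportions carry exact binomial (Clopper–Pearson) 95 %
CIs. The empirical ROC uses one point per distinct score, so its
trapezoidal integral equals the tie-aware pairwise concordance
(verified against a brute-force pair count and scikit-learn to 1e-12).
A packaged ordinal contingency table (per-grade positives/negatives
(0,2), (0,8), (6,4), (61,30), (14,1); 81 positives, 45 negatives)
reproduces the grade-only baseline: every tabulated percentage at the
≥ 25 %, ≥ 50 % and ≥ 70 % thresholds, and AUC 0.68.

## Synthetic cohort

The generator's purpose is parameter recovery: the pipeline must
recover a known lesion signal, and find nothing when there is none.

Each patient is an ellipsoidal myocardial shell (semi-axes ≈ 10 × 13 ×
13 mm, wall 4 mm) in a 32 × 48 × 48 voxel grid at 1 mm spacing, with
blood pool inside and chest-like background outside. Tissue levels are
drawn per patient — myocardium 100 ± 5 HU, blood pool 400 ± 20 HU,
background −50 ± 10 HU — emulating residual variation under a
standardized contrast protocol; voxel noise is Gaussian with
SD 20 HU. Functionally significant patients carry a raised-cosine
hypo-attenuating angular sector covering 30 % of the shell
circumference with peak depression `effect_size` (default 40 HU, the
high end of rest-perfusion-deficit contrast). All patients share one
template shell geometry: anatomical variability (size, shape, pose) is
deliberately **not** emulated, so the lesion is the only
class-correlated image structure. Clinical ground truth is generated
backwards from the label: 85 % of positives through a culprit vessel
with FFR in [0.55, 0.80], the rest through a ≥ 90 % DS vessel on
angiography with all FFR > 0.80 (FFR not measured in that vessel);
negatives draw FFR in [0.82, 0.95] and DS < 90 everywhere; values are
rounded to clinical precision (FFR two decimals, DS one). Grade
composition, prevalence and per-grade positive rates default to the
study-shaped cohort (2/8/10/91/15 patients per grade, 81/126 positive,
no positives below 25 % DS), met exactly by largest-remainder
allocation whenever exact counts are requested. One to three vessels
per patient exercise the max-grade logic; ~18 % of patients carry a
prior-event flag. All randomness flows from one cohort seed through
per-patient spawned streams, so generation is bit-identical and
order-independent, and the noise stream is label-independent (zero
effect ⇒ identical images for either label).

What passing tests therefore show: the pipeline recovers a strong,
geometrically simple perfusion-deficit-like signal against intensity
nuisance and noise, and degrades to chance without it. What they do
not show: performance under anatomical variability, partial-volume
effects, motion or reconstruction artifacts, or any claim about the
clinical discriminating signal, which in real data is unknown and
likely far subtler.

## Numerical choices and degenerate inputs

* All network arithmetic is float64 with explicitly seeded
  `numpy.random.Generator` streams (Philox); Adam with lr 1e-3;
  training is bit-reproducible for a fixed seed.
* CNN/CAE inputs use one fixed affine intensity scaling
  ((HU − 100)/200) after landmark standardization.
* Patch extraction uses mirror reflection (no edge repeat) everywhere;
  integer scales use exact gathers, non-integer scales linear
  interpolation.
* Degenerate cases are errors, not silent defaults: empty masks
  (training, encoding, QC-failed patients), single-class training
  sets, non-compressing bottlenecks, stratification with fewer
  minority patients than folds, metrics with zero denominators
  (reported absent), ND-only patients (flagged for exclusion).
* Maximum grade over vessels ignores ND; ties in scores are handled by
  shared ROC points (trapezoid = concordance).
* The zero-denominator, all-tied ROC edge (constant scores) yields
  AUC 0.5 by construction.

## Known limitations

* The segmentation and characterization networks are deliberately
  small; they are faithful in structure (two-stream multiscale
  triplanar CNN; conv auto-encoder) but not in capacity to
  GPU-scale implementations.
* The statistic set summarizing encodings is a fixed, conservative
  choice (location/scale/extremes per dimension); no learned pooling.
* Per-voxel encodings are computed from 2D in-plane patches; no 3D
  context in the characterization stage.
* The phantom is a single-template anatomy; see above for what that
  implies about external validity.
* The combined method's operating point is a configurable probability
  threshold (default 0.5); no threshold optimization is performed.
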