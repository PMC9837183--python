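# Methods

`bcseg` re-creates, on synthetic data, a clinical analysis chain for bladder
cancer on diffusion-weighted MRI: automatic tumor segmentation with a
cross-validated U-Net ensemble, followed by a reproducibility analysis of
radiomics features extracted from apparent-diffusion-coefficient (ADC) maps
under manual versus automatic delineations.  This note records the models,
the parameters that matter, and the choices made where the design was open.

## Synthetic DWI phantoms

Each case consists of three aligned volumes — DWI at b = 0 and
b = 1000 s/mm² and an ADC map — over four compartments: background, bladder
wall (ellipsoidal shell), urine-filled lumen, and one or more tumors growing
from the wall into the lumen.  Signals follow the mono-exponential decay law
S(b) = S0·exp(−b·ADC).  ADC is stored in units of 10⁻³ mm²/s, so at b = 1000
the decay exponent is simply −ADC; with the radiomics bin width of 0.005 a
tumor ROI spans on the order of a hundred gray levels, as intended for
fixed-bin-width discretization on a clinical ADC scale.

Default tissue parameters (S0 in arbitrary units, ADC in 10⁻³ mm²/s):

| compartment | S0   | ADC | within-tissue SD (ADC) | rationale |
|-------------|------|-----|------------------------|-----------|
| background  | 30   | 2.0 | 0.10 | near-noise-floor air/soft tissue |
| bladder wall| 200  | 1.6 | 0.12 | muscle-like T2 and diffusion |
| urine       | 1000 | 3.0 | 0.08 | free water: bright b0/ADC, dark b1000 |
| tumor       | 450  | 0.9 | 0.18 | restricted diffusion: bright b1000, dark ADC |

These satisfy the two contrasts that drive the clinical reading: tumor ADC <
urine ADC, and tumor b1000 signal above urine b1000 signal.  The tumor's
intra-lesion ADC spread of 0.18 makes an ROI span a few hundred gray levels
at the 0.005 bin width — the regime that discretization setting is meant
for.  Acquisition noise is Rician (magnitude MRI; Gaussian fallback
available) with default σ = 25, giving a tumor/urine contrast-to-noise
ratio of about 5 at b = 1000.  The b0/b1000 volumes carry the noise; the
ADC map is recomputed from the noiseless decay, emulating a scanner-side
fit, so the stored ADC equals the simulated tissue ADC voxel-for-voxel
(this exactness is asserted in tests).

The *cohort* generator adds features of real two-center populations that a
single phantom omits:

* **Between-patient heterogeneity.** Tumor ADC is drawn per patient from
  N(0.9, 0.13) (clipped to 0.6–1.4), compartment S0 scales vary by ±10–15%,
  intra-lesion heterogeneity varies about two-fold, and each lesion gets its
  own texture correlation length (0.5–5 mm smoothed variability field
  instead of white noise).  Agreement statistics such as the ICC are ratios
  of between-subject variance to total variance; a cohort of identical
  patients has no between-subject variance and therefore no meaningful ICC,
  regardless of how good the segmentations are — and a cohort whose lesions
  all share one texture process has no between-subject variance for
  correlation-type texture features in particular.
* **Acquisition variability and partial-volume blur.** The clean S0/ADC
  fields are smoothed with a Gaussian point-spread function specified in
  physical units (σ = 2.25 mm ≈ 5 mm FWHM, a typical effective resolution
  for clinical echo-planar DWI; converted to voxels per grid so the blur is
  grid-independent), and both the PSF and the noise level are drawn per case
  (±30–40%), emulating a multi-vendor, multi-field-strength population.
  Without blur, tissue boundaries are razor-sharp and a mask that disagrees
  with the reference by one voxel already contains full-contrast urine,
  which no real delineation disagreement produces.

Tumor geometry is a union of randomized ellipsoids seeded on the lumen
boundary; multiple tumors are placed at well-separated angles and validated
to remain disconnected (26-connectivity).  A requested tumor larger than the
lumen is rejected.  Slice count defaults to 16 at the native grid and 8 at
the reduced grid; spacing derives from a fixed 48×192×192 mm field of view
so any grid size samples the same anatomy.

The "decoy" variant adds three intraluminal lesions that match the tumor's
signal in exactly one channel each (same b1000, same b0, or same ADC) while
differing in the others.  By construction no single sequence can separate
tumor from its matching decoy; only the joint (b0, b1000, ADC) profile is
unique.  This is the instrument used to demonstrate the advantage of
multi-sequence input.

**What passing tests on phantoms do not show:** the phantoms have no motion,
no bladder deformation, no ghosting or distortion artifacts, no T2
shine-through, no multi-vendor intensity differences, and geometric rather
than perceptual delineation disagreement.  Results on them validate the
machinery (model, ensemble, features, statistics), not clinical performance.

## Preprocessing

Axial slices are resized to the square model grid (128×128 by default;
clinical DWI matrices run 110–192 × 80–128).  Intensities are bilinear with
anti-aliasing when shrinking; masks are nearest-neighbor so they stay
binary.  Non-square slices are stretched anisotropically — no padding.

Signal intensities are normalized per sequence and per patient volume as
(SI − mean)/(12·SD).  The 12× divisor is kept as a configurable constant;
the normalization scope (whole 3D volume rather than per slice or per
dataset) is our documented choice — per-slice normalization would erase
inter-slice contrast.  The transform is exactly invertible given the stored
statistics, and a constant volume raises rather than emitting NaNs.

Model input is three channels: in `multi` mode the normalized (b0, b1000,
ADC) volumes in that order; in a single-sequence mode the chosen sequence
replicated three times.

## Segmentation model

A 2D U-Net with **five resolution levels** (one deeper than the classic
four-level design): per level two Conv(3×3)–BatchNorm–ReLU blocks, 2×2 max
pooling on the way down, 2×2 stride-2 transposed convolutions and skip
concatenations on the way up, and a 1×1 convolution + sigmoid head.  Channel
width doubles per level from `base_filters` (default 32; the full-scale
schedule is 30 epochs, batch 56, Adam at lr 0.001 on the 128 grid).  "Five
levels" is interpreted as five resolutions (four poolings), which keeps an
8×8 bottleneck at 128×128 input.

The network, its backward pass, and Adam are implemented directly in NumPy
(im2col convolutions backed by BLAS matrix multiplication, float32).  The
backward pass is verified against float64 finite differences to ~1e-8
relative error in the test suite.

Two numerical choices matter in practice:

* **Prior-matched head initialization.** The head weights are scaled down
  and its bias set to −2.5, so the initial foreground probability (~8%) is
  close to the rare tumor prior without being so small that the early
  Dice-loss gradient (∝ p(1−p)) vanishes.  With a standard initialization
  the sigmoid saturates toward 1 on large regions and training stalls for
  many epochs; with too negative a bias, small training folds can stay in
  the empty-prediction basin.
* **Cosine learning-rate decay** from the configured initial rate to zero
  over the epoch schedule; without it, late-training Adam steps at small
  batch sizes oscillate between epochs.
* **Soft-Dice loss per sample**, 1 − (2Σpt + s)/(Σp + Σt + s) with smoothing
  s = 1, averaged over the batch.  For binary predictions and s → 0 this is
  exactly one minus the Dice similarity coefficient (asserted cross-module).

Cross-validation is five-fold at the **patient level**: a random partition of
patients into folds of near-equal size (±1), all slices of a patient on one
side of every split; leakage is asserted in tests.  Folds are unstratified.
Validation probabilities are binarized at 0.5 (ties included).

A reduced profile (`TEST_SCALE`: base_filters 8, epochs 10, batch 8, 64×64
grid) ships for CPU-scale runs; all end-to-end experiments in the test suite
and the acceptance script use it.  Problem sizes there — 50 phantoms of
8×64×64 voxels, 40 for cross-validation and 10 held out — are the package's
desk-scale defaults.

## Ensemble and evaluation

Held-out cases are segmented by all five fold models; a voxel is tumor when
**at least 3 of the 5** member masks agree (configurable).  The consensus is
bounded between the members' intersection and union by construction.

Overlap is the Dice similarity coefficient DSC = 2|T∩P|/(|T|+|P|), computed
volumetrically per patient (not per slice).  Conventions: two empty masks
score 1.0, exactly one empty mask scores 0.0 — this keeps aggregates
NaN-free and is asserted in tests.  Cross-validation results are summarized
as mean and (min, max) over folds; held-out results as median and
interquartile range with linear-interpolation quartiles.

## Radiomics (107 features)

Features follow the reference taxonomy: 18 first-order, 14 shape, and 75
high-order texture features (GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14),
extracted in 3D from the ADC map under a binary ROI.  Settings mirror the
reference defaults except bin width 0.005 and voxel-array shift 1:

* **Discretization**: fixed bin width W = 0.005, levels floor((x − min)/W)+1
  anchored at the ROI minimum (with a 1e-9 guard against floating-point
  quotients landing just below an integer).  Anchoring at the minimum makes
  all texture families invariant to adding a constant to the ROI (tested).
* **Shift**: +1 applied only to the energy-type first-order features
  (Energy, TotalEnergy, RootMeanSquared).
* **Aggregation**: distance-1 neighborhoods, the 13 unique 3D directions,
  symmetric GLCM normalized per direction, features averaged over directions
  (directions without voxel pairs are skipped).  GLSZM zones use
  26-connectivity and are orientation-free.  GLDM uses dependence threshold
  α = 0; a voxel's dependence is its count of equal-level 26-neighbors, and
  the feature formulas weight dependence size as count + 1 (the center
  counts itself).
* **Shape**: surface mesh from marching cubes at iso-level 0.5 on the padded
  mask in physical coordinates; mesh volume by the divergence theorem; axis
  lengths 4·√λ from the sample covariance of voxel coordinates; maximum
  diameters as largest pairwise vertex distances in 3D and in the three
  projection planes (convex-hull reduction for speed).  Note that meshes of
  voxelized solids overestimate surface area by ~8% (staircase effect), so
  the sphericity of a digital ball plateaus near 0.92 rather than 1; volume
  and diameters do converge to the analytic values.  Single-voxel masks get
  zero axis lengths and zero elongation/flatness rather than an error.
* **Degenerate conventions** (frozen in tests): a single-gray-level ROI has
  GLCM Correlation = MCC = 1 and Imc1 = Imc2 = 0; NGTDM Contrast/Busyness
  are 0 with one gray tone; Coarseness is capped at 1e6 when its denominator
  vanishes; first-order Skewness/Kurtosis are 0 for constant ROIs.
* **MCC** is computed, for the symmetric co-occurrence matrix, as the
  second-largest |eigenvalue| of D^(−1/2) P D^(−1/2) (equivalent to the
  second eigenvalue of the usual Q = (D⁻¹P)² and numerically far cheaper);
  equivalence with the directly-built Q is asserted against a loop oracle.

Every feature value is validated against an independent brute-force
implementation (literal loops over the published formulas) on small random
ROIs; the five texture-matrix constructions are additionally checked exactly
against hand-enumerable oracles on ≤3×3×3 grids.

## Reproducibility statistics

Agreement between features from manual (reference) and automatic (ensemble)
ROIs is ICC(2,1): two-way random-effects ANOVA, absolute agreement, single
measurement,

ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

with the F test of the target effect (F = MSR/MSE, df (n−1, (n−1)(k−1))) and
a 95% F-distribution confidence interval (Shrout–Fleiss/McGraw–Wong form
with Satterthwaite degrees of freedom; bounds clamped to [−1, 1] for
pathological anti-agreement tables).  "ICC 2.1" is read as absolute
agreement in the Shrout–Fleiss scheme; the estimator matches both a
first-principles ANOVA oracle (1e-10) and pingouin's ICC(A,1) in tests.
A constant table is flagged degenerate instead of returning NaN mean
squares.  Estimates are binned poor < 0.50 ≤ moderate < 0.75 ≤ good ≤ 0.90 <
excellent; the published bin endpoints overlap, so the half-open assignment
above is frozen here and tested.  Significance is p < 0.05 with no
multiple-testing correction.

Per-family summaries report median and IQR of the per-feature ICCs, with
family sizes validated against the 18/14/24/16/16/5/14 manifest.

For controlled experiments, `perturb_mask` emulates delineation disagreement
by adding a smooth Gaussian random field (correlation length 2 voxels),
scaled by a magnitude parameter, to the mask's signed distance transform
after a small random translation; expected overlap with the original
decreases monotonically in the magnitude (Monte-Carlo tested), and
`calibrate_perturbation` bisects the magnitude to a target mean DSC (0.85 in
the reproducibility experiments).  Under that calibration the phantom cohort
shows high median reproducibility for shape and the size/dependence texture
families (≈0.85–0.98), moderate for first-order intensity statistics, and
borderline (≈0.4–0.6, varying with the cohort seed) for GLCM and NGTDM —
qualitatively the same ordering as the clinical analysis this emulates,
where GLCM was also the widest-spread family.  The borderline families are
second-order difference statistics whose disagreement under a *geometric*
perturber is dominated by boundary contamination against the much brighter
urine; an intensity-driven segmenter, which follows image boundaries, is a
gentler second rater for exactly these features.

## Pipeline and reproducibility of runs

`run_pipeline` chains the stages on one config: simulate cohort → patient
-level train/test split (default 18% held out, emulating a 140/30 design) →
five-fold cross-validated training → ensemble segmentation of the test set →
DSC report → radiomics under manual and automatic masks → per-feature ICC and
family summaries.  Every stochastic stage is seeded from the single master
seed, so a rerun of the same config reproduces all reports exactly; reports
are tidy CSVs plus a JSON run log of seeds and stage timings.  Test cases
whose automatic mask is empty drop out of the agreement analysis (logged);
the run aborts if fewer than two remain.

## Known limitations

* The NumPy network trains on CPU at desk scale only; the full-scale
  schedule (30 epochs, batch 56, base 32 at 128×128 on 140 patients) is
  expressible in config but is not what the shipped experiments run.
* Phantom realism limits are listed above; in particular, geometric mask
  perturbation is a harsher "second rater" than an intensity-driven
  segmenter, since it ignores image boundaries.
* Mesh-based shape features carry the voxelization surface-area bias of
  marching cubes on binary masks.
* 2D per-slice radiomics aggregation, filtered-image (wavelet/LoG) features,
  alternative fusion rules (probability averaging, STAPLE), and comparison
  segmentation architectures are out of scope.
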