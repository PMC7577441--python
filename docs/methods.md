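# Methods

## The measurement model

A CT volume calibrated in Hounsfield units (HU) is a 3D grid `(z, y, x)` with
z increasing toward superior. All analysis happens on integer HU clamped to
[−1024, 3071] — the full 12-bit CT range — so the 1-HU-bin histogram is a
lossless summary of a VOI and the histogram-derived mean equals the voxel
mean identically.

The proximal femur is extracted in two steps:

1. **Region growing.** The maximal 26-connected component of voxels with
   HU ≥ *t* containing an operator-supplied seed voxel. The default threshold
   *t* = 126 HU doubles as the dense-bone histogram boundary: it lies far
   above soft tissue (≈ 40 HU) and far below cortex (≈ 1000+ HU), so on
   uncorrupted data the grown region is the mineralized skeleton connected to
   the seed. The commercial tools this replaces do not publish their growth
   criterion; a fixed lower threshold is the simplest criterion with the
   right behaviour and is fully reproducible.
2. **Envelope filling.** Marrow voxels are fat-attenuating (HU ≤ 0) and are
   excluded by any bone threshold, yet the analysis must include them. Every
   background cavity not 6-connected to the volume border is therefore added
   to the mask. The standard 26/6 foreground/background connectivity pair
   avoids the tunnel paradoxes of digital topology; filling is idempotent and
   monotone (input ⊆ output).

The VOI is the envelope at or above a single axial cut plane — the inferior
margin of the lesser trochanter — supplied by the operator as a slice index
or a physical z coordinate (nearest slice, half-way ties toward superior).
Landmark placement is deliberately manual: observers set it visually in
practice, and automating it would be a separate segmentation problem.

On the VOI the package reports total volume (voxels × voxel volume), mean HU,
and the HU-histogram fractions: `huha_fat` = % of voxels with HU ≤ 0,
`huha_dense` = % with HU ≥ 126, `huha_mid` the complement, so the three sum
to 100 by construction. Both thresholds are inclusive; 0 HU counts as fat
(`fat_strict=True` gives the strictly-negative variant). Serialized CSV
reports round to 0.01 (cm³, %, HU); JSON keeps full precision and
round-trips exactly.

Known failure mode: if noise or disease bridges the femur to the acetabulum
at the threshold, the grown region spans the joint. The package reports the
envelope voxel count so this is visible, but does not attempt automatic
joint separation; raise the threshold or edit the mask.

## Agreement and power statistics

- **ICC(A,1)** (McGraw & Wong): from the two-way crossed ANOVA mean squares
  (subjects MSR, raters MSC, residual MSE),
  `ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))`, with the
  standard F-based 95% CI. The mixed-vs-random distinction does not change
  the point estimate. Categories: < 0.50 poor, 0.50–0.75 moderate,
  0.76–0.90 good, > 0.90 excellent. A perfectly agreeing table (MSC = MSE
  = 0) returns ICC 1 with a degenerate CI; a zero-variance table is an error.
- **Bland–Altman**: mean difference ± 1.96·SD (SD with n−1 denominator).
  The 1.96 multiplier is fixed (not a t-quantile), matching how such limits
  are conventionally reported. Differences are always first − second and the
  result carries that orientation tag, because published summaries of the
  same comparison can disagree in sign.
- **Paired t** (`t = mean_diff / (sd_diff/√n)`, df n−1) and **Welch t**
  (Satterthwaite df). Normality screening is not automated; both tests are
  exposed and the caller chooses. A constant nonzero difference is
  degenerate (no sampling variance) and raises.
- **Power / sample size** use the exact noncentral t distribution
  (noncentrality `d·√n`, df n−1), not the normal approximation; the sample
  size is the smallest n whose power reaches the target (bracket + bisect on
  the monotone power curve). At d = 0.5, α = 0.05 these give 93.4% power
  two-tailed at n = 50 and a minimum n of 45 for 95% one-tailed power — the
  two design calculations a 50-patient paired study implies. (A two-tailed
  95% target would instead require n = 54; both readings are computable.)

## The phantom generator

`PhantomSpec` defines a stylized femur: a spherical head (default radius
22 mm), an oblique capsule neck (radius 12 mm, length 40 mm, 45° in the z–x
plane), a vertical capsule shaft (radius 14 mm) and an ellipsoidal
lesser-trochanter bump whose inferior margin sits at the VOI cut plane
(default 40 mm above the inferior face), embedded in an elliptical
soft-tissue body inside air, on a 128×80×120 grid at 1 mm isotropic spacing —
the slice thickness/interval of typical archived reconstructions, with radii
in the range of adult female femora. A cortical shell of fixed physical
thickness (3 mm, via Euclidean distance transform) encloses an interior
whose voxels are fatty marrow with probability `marrow_fat_fraction`
(default 0.35 — largely fatty marrow, as in older adults) and trabecular
bone otherwise.

Default compartment means: air −1000, soft tissue +40, fatty marrow −80,
trabecular +250, cortical +1100 HU; per-compartment SDs default to 0 so the
noise-free phantom is exactly piecewise constant and its composition
fractions are exact by counting. Scanner noise is additive white Gaussian
(default SD 25 HU; the noisy validation studies use 50 HU) applied after
label assignment; values are rounded to integer HU and clamped. Identical
spec + seed reproduces the volume bit-for-bit.

What the phantom deliberately omits: trabecular microarchitecture, partial
volume and PSF blur, beam hardening, spatially correlated noise, anatomic
shape variation. Marrow voxels are assigned independently rather than in
spatially clustered lobules, because the histogram statistics depend only on
composition, and independence keeps the expected fractions in closed form.
Passing tests therefore demonstrate correctness of the *measurement
machinery* under a known composition model, not segmentation robustness on
clinical anatomy.

Under rounding to integer HU, a compartment with mean μ and total noise SD σ
contributes `Φ((0.5 − μ)/σ)` to the expected fat fraction and
`Φ((μ − 125.5)/σ)` to the expected dense fraction (half-integer continuity
points); `expected_threshold_fraction` evaluates these per-compartment
Gaussian tails. At 50 HU noise the pipeline's measured HUHA_fat sits
slightly (~0.3 percentage points) below this prediction: region growing
accretes the few supra-threshold soft-tissue boundary voxels, which are
never fat, mildly diluting the fat fraction. This bias is inherent to
threshold-grown envelopes on noisy data and is kept visible rather than
corrected away.

**Contrast enhancement** is modelled as additive per-compartment HU shifts
(default all 0; bone shifts small or zero, reflecting the sparse blood
supply of the femoral head that motivates femoral opportunistic screening on
enhanced scans). On a fixed noise realization a positive trabecular/marrow
shift can only move voxels upward across the 0 and 126 HU boundaries, so
HUHA_fat falls and HUHA_dense rises in every case — the qualitative pre/post
pattern the statistics modules are exercised on.

**Cohorts.** `sample_cohort_specs` jitters the geometric radii/lengths by a
few percent (SDs ≈ 5% of each dimension, truncated at ±20%) and reseeds each
subject, providing the between-subject variance without which reliability
coefficients are undefined. **Rater tables** are simulated from the additive
two-way model `y_ij = μ + s_i + b_j + ε_ij`, whose population
single-measure absolute-agreement ICC is σ²_s/(σ²_s + σ²_b + σ²_e) and is
recorded alongside the table. Note that with k = 2 raters the realized
rater-bias spread in any single table is a 1-df draw, so a single table's
estimate scatters around the analytic value; recovery studies therefore
average the estimate over replicate tables (20 tables of n = 2000 in the
validation suite).

## Numerical and design choices

- Volumes store int16 HU; rounding happens once, at construction.
- EDT-based cortex definition (distance to background > thickness) rather
  than analytic shell geometry: exact on the voxel lattice and
  oracle-checkable by brute-force minimum distance.
- The region-growing oracle in the tests is an independent breadth-first
  flood fill; the ICC oracle is explicit sum-of-squares arithmetic; power is
  cross-checked against an independent noncentral-t implementation, and ICC
  point estimate/CI against a second published implementation.
- Study sizes in the validation suite (50 phantoms at the default grid, 20
  replicate rater tables of n = 2000, 200 random 7³ flood-fill volumes) were
  chosen to make Monte-Carlo error small relative to the tolerances they are
  checked against while keeping the whole suite fast.
- Degenerate inputs fail loudly and specifically: sub-threshold seeds, empty
  masks or VOIs, incomplete rater rows (dropped listwise with a warning, the
  agreement formulas assume complete tables), zero-variance tables, constant
  nonzero paired differences.
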