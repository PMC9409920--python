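# Methods

## Pipeline

For each patient: four co-registered 2D modality slices (CET1WI, T2FLAIR,
DWI, ADC), a tumor ROI and a brain mask.  The fixed processing order is

1. **ROI intersection** — when two readers' masks are supplied, their
   pixelwise AND is used; an empty intersection is an error.
2. **Alignment** — every modality is resampled onto the CET1WI grid by
   bilinear interpolation, both grids treated as spanning the same field of
   view with pixel centers at (i + ½)/n of the extent.  Border cells are
   linearly extrapolated, which keeps the operation exact for planar
   intensity fields; no registration search is performed (inputs are assumed
   co-registered).
3. **Background removal** — pixels outside the brain mask are set to 0.
4. **Normalization** — in-mask intensities are discretized to integer levels
   1..100 by equal-width binning over the in-mask min–max range
   (`level = floor((v − lo)/(hi − lo)·100) + 1`, clipped).  0 is reserved for
   background.  Statistics are taken over the whole brain mask, not just the
   ROI, because normalization precedes the transforms.  Both extreme levels
   are always attained, so the map is idempotent and invariant to positive
   affine intensity rescaling.  Equal-width fixed-bin-number discretization
   is the standard radiomics choice; a piecewise-landmark scheme could be
   substituted behind the same interface.

## Transforms

**Haar DWT (one level).**  Separable orthonormal Haar on non-overlapping 2×2
blocks: A = (a+b+c+d)/2, H = (a+b−c−d)/2 (variation along rows), V along
columns, D diagonal.  Energy is conserved exactly; the inverse is exact.
Odd dimensions are edge-replicated to even, and the padding is recorded and
cropped on inversion.

**DTCWT (one level).**  The standard first-level dual-tree construction: a
real biorthogonal wavelet tree plus a second tree whose filters are the same
pair delayed by one sample.  A one-sample delay before decimation equals
taking the other polyphase phase, so both trees are computed at once as an
*undecimated* separable filtering followed by a 2×2 polyphase split.  The
filters are the LeGall 5/3 analysis/synthesis pairs (odd-length, symmetric,
zero-phase), recorded in `wavelets.ANALYSIS_LO/HI` and `SYNTHESIS_LO/HI`.
Per detail band the four (row-phase × column-phase) quads combine unitarily,

    p = (a + jb)/√2,  q = (d − jc)/√2,  z∓ = p ∓ q,

into six complex subbands labelled {+15, +45, +75, −75, −45, −15} degrees
(angles measured from the horizontal axis, counter-clockwise as displayed,
row index downward; the label→combination mapping was fixed once by grating
probes and is pinned by the selectivity tests).  The unitary combination
conserves detail-band energy, and the transform inverts exactly: undecimated
biorthogonal synthesis only needs H₀G₀ + H₁G₁ = 2, which the 5/3 pair
satisfies identically, and whole-sample mirror extension with zero-phase
symmetric filters is self-consistent at boundaries.  Round-trip error is at
machine precision (~1e-15), well inside the 1e-8 contract.

The six **magnitude** images (the standard near-shift-invariant choice; the
source protocol does not specify magnitude vs real part) plus the four DWT
bands and the pre-transformed image give 11 derived images per modality, 44
per patient.  The DTCWT lowpass is retained for inversion but is not a
feature image.  ROIs follow subband geometry by any-overlap 2× downsampling.

### Level-1 band structure — a real constraint

A one-level detail band covers per-axis frequencies roughly [π/2, π], i.e.
wavelengths of 2–4 px.  Two consequences, both verified analytically and by
measurement:

* A ±45° grating only concentrates in the diagonal subbands when *both* axis
  frequencies exceed π/2, i.e. for periods below 2√2 ≈ 2.8 px.  At period 8
  such a grating sits in the lowpass band and its residual detail energy
  leaks into the ±15/±75 bands for any halfband filter pair.  The
  selectivity suite therefore probes ±15/±75 at period 3 and ±45 at period
  2.5, where the matched subband ranks first (energy shares 0.70 and 0.47).
* Magnitude near-shift-invariance relies on the one-sample-delay Hilbert
  pairing, which is exact at ω = π/2 and degrades toward the band edges.
  On white or lightly-correlated textures the per-band magnitude energy
  changes by ~1–2% under a 1 px shift, 3–4× more stable than Haar detail
  energies; on strongly lowpass textures (Gaussian σ ≳ 1) the residual
  in-band energy is small and badly paired, and the advantage reverses.
  This is a known level-1 limitation, not an implementation artifact.

## Features

Six first-order statistics over ROI pixels of each derived image
(4 × 11 × 6 = 264 per patient), population-moment conventions (MATLAB-style
defaults): mean; CV = σ/μ (population σ; 0 if μ = 0, unreachable on
normalized images whose levels start at 1); skewness and raw kurtosis
(Gaussian → 3); energy = plain sum of squares; entropy in bits over a
100-bin equal-width histogram spanning [min, max] (the bin count reuses the
normalization setting).  σ = 0 yields the sentinels skewness = kurtosis =
entropy = 0 rather than NaN, so the table is always complete.  Under
x → cx (c > 0): mean scales by c, energy by c², the rest are invariant;
under x → x + d: skewness/kurtosis/entropy invariant, CV not.  Canonical
column names are `modality/transform/component/statistic`
(e.g. `T2/DTCWT/+45/kurtosis`), ordered modality (T1, T2, DWI, ADC), then
transform (PRE < DWT < DTCWT), then component, then statistic.

## Screening and classification

Per feature, a pooled-variance two-sample Student t-test (Welch behind a
switch) between the classes; survivors have two-sided p strictly below
α = 0.001, with no multiple-testing correction (a faithful reproduction of
the raw-p protocol, not an endorsement).  Zero-variance features get p = 1
and a degenerate flag.

Within each transform family every nonempty subset of the surviving features
is evaluated: stratified 5-fold cross-validation (per-class round-robin after
a seeded shuffle; fold totals differ by ≤ 1), per-fold standardization by
training-fold mean/sd (a scale-sensitive linear SVM requires it; constant
features standardize to 0 with a warning), linear SVM with C = 1, and pooled
out-of-fold predictions.  One fold assignment per search, so subsets share a
common partition.  Metrics: ACC/SEN/SPC/F1 from the pooled confusion counts
(positive class = GBM-like), AUC as the Mann–Whitney statistic with half
credit for ties.  Winner by accuracy, then AUC, then smaller subset, then
enumeration order (the tie-break chain is this package's choice).  Intervals:
Wilson score for proportions, stratified percentile bootstrap (2000 reps,
seeded) for AUC — both conventional choices where the protocol is silent.
Groups larger than 25 features require an explicit `max_subset_size`; the
combined all-family search is gated behind a flag.

Because the reported winner is selected on the same pooled out-of-fold
predictions it is scored on, searched-best metrics are optimistically biased;
the suite measures this directly (mean searched-best accuracy on label-free
noise exceeds the 27/51 majority rate).

## Phantom generator

Each patient is a 128 px square slice (tests use 64 px): an elliptical brain
with a ring "skull" inside the brain mask, a disk tumor with a 3 px rim, and
Gaussian pixel noise (σ = 5) on piecewise-constant tissue levels.  Per-patient
variation: tumor radius U(12, 20) px, tumor center jitter, a N(0, 2) baseline
intensity offset.  Class effects, and only these, distinguish the groups:

* **CET1WI rim**: rim level 140 + `rim_contrast_delta` (default 15 = 3σ of
  the noise) in the positive class — a first-order, pre-transform signal.
* **T2FLAIR texture**: an oriented cosine grating added inside the ROI of
  positive patients, default +15°, amplitude 10 (2σ), period 3 px — chosen
  inside the level-1 detail band so the matched subband can see it (at the
  8 px period used for illustration elsewhere the texture lands in the
  approximation band and only DWT-A statistics detect it).

DWI/ADC are smoothed anatomy companions with independent noise and no class
signal.  With both effects zeroed the classes share one generating
distribution, which calibrates the screen (null p-values uniform; the
p < 0.001 screen selects ≈ 0.1% of features).  The phantom has no anatomical
realism, scanner physics, registration error, intensity nonstationarity, or
3D structure, so passing tests demonstrate the statistical machinery and the
transforms' contracts — not clinical performance on real MRI.  Default
effect sizes make the phantom linearly separable; they exercise every
pipeline contract but leave headline metrics saturated at 100%.

The family-comparison experiment (oriented texture as the only signal) uses
fixed equal-size groups — the six T2 pre-transform statistics vs six T2
±15° DTCWT statistics — rather than data-driven top-p groups: unequal
candidate pools (24 vs 144 features) would inflate the larger family's
searched-best accuracy on pure noise, biasing the comparison by
construction.  With fixed groups both families have identical search
capacity (63 subsets), the DTCWT family wins or ties in every replicate
under texture signal, and the two are indistinguishable under the null.

## Numerical and design notes

* Problem sizes in the suite: 64 px cohorts, 20 seeded replicates for
  Monte-Carlo claims, 1000-vector statistic oracles, 5000-feature null
  calibration — the sizes at which the asserted margins are comfortably
  stable.
* Determinism: all randomness flows through `numpy` `SeedSequence` children
  (per-patient streams) or explicit seeds (folds, bootstrap); identical
  config + seed reproduces cohorts bit-for-bit and reports byte-for-byte.
* Degenerate inputs: empty ROI/mask → error; constant images → zero detail
  bands and level-1 normalization; k = N folds allowed as leave-one-out.
* The 5/3 filter choice favors perfect reconstruction, symmetry, and speed;
  it is not matched to any particular legacy implementation, so absolute
  feature values may differ from other DTCWT codebases even though every
  structural and statistical contract holds.  Longer near-symmetric pairs
  can be substituted by editing the four filter arrays, provided
  H₀G₀ + H₁G₁ = 2 and all filters are odd-length symmetric.
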