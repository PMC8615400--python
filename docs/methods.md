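# Methods

This note documents the models, conventions and numerical choices behind
`crosspet`, and what the synthetic experiments do and do not demonstrate.

## SUV preprocessing

SUV uses the body-weight convention: `SUV = C · w / D(t)` with activity
concentration `C` in Bq/mL, weight `w` in grams, and the injected dose
decayed from injection to the scan reference time,
`D(t) = D₀ · 2^(−Δt/T½)` (¹⁸F default T½ = 6586.2 s). The reference time
is a parameter: when two acquisitions follow a single injection, the
second scan can be corrected to the first scanner's time point. Lean-body-
mass variants are out of scope.

Resampling to the isotropic analysis grid (default 1.5 mm) is trilinear
(`scipy.ndimage.zoom`, endpoint-preserving grid convention), order 1 being
the conservative choice for PET: higher-order splines can ring at the
sharp lesion boundary and produce negative uptake. Any residual negative
values are clamped to zero for SUV volumes. Masks are resampled by nearest
neighbour (they are regenerated on the target grid in the synthetic
pipeline). If fewer than two voxels would remain along an axis the
operation fails rather than extrapolate.

## Segmentation

The ROI rule is the common clinical one: seed at the global (or
search-region-restricted) SUVmax, threshold at a fraction of it (default
0.5), keep the 26-connected component containing the seed. Decisions worth
recording:

- The threshold comparison is **inclusive** (≥); a strict flag exists.
  Inclusive avoids empty masks on plateau lesions where several voxels tie
  at the maximum.
- SUVmax ties resolve to the lowest linear voxel index — deterministic
  across platforms.
- The search region restricts the seed only; an optional flag also
  intersects the final component with it. Physician edits of the automatic
  contour are not modelled.
- On a resolution-blurred image the half-maximum contour sits slightly
  inside the true lesion boundary; this is physics, not an artifact (the
  tests assert Dice ≥ 0.95 against truth for sharp lesions and ≥ 0.85
  under the default blur).

## Feature panel

The roster is data (a versioned manifest CSV shipped with the package) and
is pinned to 4 conventional + 8 geometry + 9 image sets × (16 histogram +
22 GLCM + 11 GLRLM) = 453 entries. Conventions:

- **Histogram**: population variance/SD; excess kurtosis (Gaussian → 0);
  entropy and uniformity on a 64-bin equal-width histogram of the ROI
  values; energy is Σx². Skewness/kurtosis of a constant ROI are NaN with
  a degenerate flag.
- **Discretization** for texture: equal-width binning of the ROI's
  [min, max] into 64 levels (configurable); the maximum maps to the top
  level; a constant ROI is flagged degenerate. Equal-width binning makes
  texture features invariant under monotone affine intensity maps, which
  the tests assert.
- **GLCM**: one symmetric matrix pooled over the 13 unique distance-1
  directions (per-direction averaging behind a flag), normalized to
  probabilities. All entropies are log₂ with 0·log 0 = 0; the second
  information measure of correlation uses the classical
  `sqrt(1 − exp(−2(HXY2 − HXY)))` form (base-independent). Sum variance is
  centred on the sum average; difference variance on the difference
  average.
- **GLRLM**: runs of equal level along the same 13 directions; out-of-ROI
  voxels break runs. Run percentage is normalized by voxels × directions,
  so it equals the per-direction average.
- **Geometry**: volume is voxel counting (reported in mL). Surface area
  uses a Crofton-style estimator, `A = (2/3) · Σ exposed-face areas`
  accumulated per axis orientation: for isotropically oriented smooth
  surfaces the summed axis-projected face area converges to 3/2 of the
  true area, making the estimator asymptotically exact for digitized balls
  (mean error < 1 % at 1.5 mm for radii ≥ 6 mm, decaying with radius) where
  a raw marching-cubes mesh overestimates curved surfaces by ~10 % with no
  convergence. A single-voxel ROI reports its voxel-cuboid area. Because
  sphericity, compactness 2 and spherical disproportion are functions of
  the same (A, V), they satisfy `compactness2 = sphericity³` and
  `disproportion = 1/sphericity` exactly.
- **Wavelet**: single-level separable 3-D transform, Coiflet-1 by default,
  **undecimated** (stationary) so every subband is congruent with the ROI
  mask; odd axes are symmetrically padded to even length and cropped back.
  Subband labels read axis 0 first (LLH = low-pass along axes 0 and 1,
  high-pass along axis 2). Histogram statistics on subbands use the raw
  signed coefficients; texture re-discretizes each subband over its own
  ROI range. A decimated orthogonal mode exists for energy bookkeeping
  (Parseval holds exactly there; the undecimated frame is redundant and
  does not preserve energy).

Degenerate features are NaN, flagged, and carried through — the panel
length is always 453 — then deleted pairwise in the statistics.

## Paired-device statistics

Per feature, with x = device A and y = device B on the same subjects:
ordinary least squares `y = a·x + b` (`scipy.stats.linregress`; r² is the
squared Pearson correlation, identical to the coefficient of determination
for simple OLS), and ICC(3,1) in the consistency form
`(MS_R − MS_E)/(MS_R + MS_E)` from the two-way subjects × devices ANOVA
with k = 2. The absolute-agreement variant ICC(A,1) is available behind a
flag; reports name the form used. Consistency is the default because a
fixed calibration offset between two specific devices should not count as
subject-level disagreement when the question is linear interchangeability.

Classification uses strict inequalities (a feature at exactly r² = 0.85 is
moderate, not strong). Features with NaNs are analysed on complete pairs;
fewer than 3 complete pairs or a constant x yields "not assessable",
counted separately from weak. The maximum Cook's distance of each fit is
reported as a leverage flag; no point is removed automatically.

Interchange equations are exported for strong + moderate features; the
inverse map `x = (y − b)/a` is algebraic, never refit. Subband-vs-original
comparisons are two-sided paired t-tests over the 49 matched feature
definitions, run separately for r² and ICC; identical vectors return
(t = 0, p = 1) by convention. No multiple-testing correction is applied by
default (raw p-values are reported); a Holm step-down is a caller-side
one-liner on the returned table.

## Synthetic paired phantoms

The generator emulates a paired-device brain-PET study at its published
scale (15 subjects by default) rather than PET physics:

- **Anatomy**: one ellipsoidal lesion (default semi-axes 12 × 10 × 9 mm)
  on a uniform background, mean uptake 5 vs 2 SUV (tumor-to-normal 2.5,
  the usual therapy-eligibility level), with intra-lesion Gaussian-random-
  field texture (correlation length ~3 mm, SD ~0.75 SUV) and a radial
  uptake profile (hot-core/hot-rim). The volume is blurred by a shared
  scanner PSF (σ = 1.2 mm) — this puts the half-maximum contour on a
  slope, so device perturbations shift the segmented boundary as they do
  in real PET — and carries mild background noise.
- **Cohort heterogeneity**: lesion size (≈3× linear range), uptake,
  texture amplitude and grain, and the radial profile vary per subject.
  Between-subject variance is what the ICC measures agreement against;
  a homogeneous cohort would make the statistics meaningless.
- **Device B** = Gaussian-smoothed (σ = 0.5 mm resolution mismatch),
  gain/offset-rescaled (1.03 / +0.05 SUV, with per-subject calibration
  scatter emulating anatomy-dependent attenuation-correction bias), plus
  white voxel noise (SD 0.1 SUV) and spatially correlated reconstruction
  noise (SD 0.15 SUV, 2.5 mm correlation length). The correlated
  component matters: white noise alone is filtered out by the low-pass
  subband, which would make LLL features agree systematically better than
  unfiltered ones; correlated noise degrades all bands alike, matching the
  empirical observation that low-pass filtering neither helps nor hurts
  agreement while high-pass filtering hurts it badly.

Defaults were sized so a full 15-subject paired extraction and comparison
completes in well under two minutes on one CPU (a single 64³ extraction
takes ~0.5 s).

What the phantom study does **not** show: real attenuation-correction
algorithms (only their smoothing/gain/noise signature), pharmacokinetics
of tracer uptake between sequential scans, partial-volume effects beyond
the PSF blur, multi-lesion anatomy, or reconstruction artifacts. Passing
tests demonstrate that the statistical pipeline recovers known ground
truth and reproduces the qualitative frequency-band ordering of
cross-device agreement — not that any particular clinical feature is
interchangeable.

## Feature-pair generator

For statistics-only tests, paired tables are drawn directly:
x ~ lognormal (right-skewed positive scales typical of radiomics),
`y = s·x + c + ε`, with `sd(ε) = |s|·sd(x)·sqrt(1/r² − 1)` back-solved
from a target r² using the realized sample SD. Ground truth (s, c, target
r²) is returned for recovery tests. Target tiers (0.95 / 0.7 / 0.3) map to
strong / moderate / weak: with slopes in [0.5, 1.5] the implied
consistency ICC stays on the correct side of each cut-off, which the
recovery tests confirm empirically at n = 200.

## Numerical conventions and edge cases

- Logarithms in entropies: base 2; 0·log 0 = 0.
- All randomness flows through `numpy.random.default_rng` seeded from the
  caller; identical spec + seed is bitwise reproducible.
- Sub-seeds are derived via `SeedSequence` and kept below 2³¹.
- Errors are typed (`crosspet.errors`): metadata, chronology, resolution,
  no-lesion, mask-conflict, parameter, degenerate-data and spec errors,
  so callers can distinguish bad input from degenerate data.

## Known limitations

- The 449-name roster is one defensible realization of the
  histogram/GLCM/GLRLM/wavelet panel; other implementations differ in
  exact feature lists and discretization, so absolute feature values are
  not comparable across toolkits (the cross-device *statistics* are).
- ICC confidence intervals are not computed (point estimates only).
- The paired t-test across 49 features treats features as independent
  samples; they are correlated, so its p-values are descriptive, as in
  common practice for this design.
- Surface-derived features on very small ROIs (a few voxels) are dominated
  by digitization; the single-voxel case is special-cased, not smoothed.
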