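# Methods notes

This note records the models, defaults and numerical choices behind the
package, and what the synthetic phantoms do and do not establish about
real scans.

## The measurement problem

Bone marrow fat in a long bone is summarized by two quantities: the bone
marrow fat fraction (BMFF, %) — the fat share of the marrow compartment —
and the bone marrow fat volume (BMFV, cm³) over an analyzed slice range.
Axial slices of thickness *t* with inter-slice gap *g* tile the bone
contiguously when each slice is assigned an axial extent of *t + g*; all
area→volume conversions use this extent (0.5 cm + 0.5 cm = 1.0 cm per
slice under the default acquisition geometry). The analyzed region is the
middle third of the bone extent: for an N-slice extent starting at index
`s`, slices `[s + ⌊N/3⌋, s + ⌊2N/3⌋)` (0-based, half-open everywhere).

## Segmentation

Each T1-weighted slice is median filtered (3×3, reflect edges) and its
intensities are clustered with fuzzy c-means (FCM). FCM is the standard
fixed-point iteration on 1-D intensities: memberships
u_ij ∝ (1/d_ij²)^{1/(m−1)} normalized per voxel, centroids the
u^m-weighted means. Defaults: k = 4 clusters (dark
background/bone, skin/red-marrow, muscle, fat), fuzziness m = 2,
tolerance 1e−5 on centroid movement, ≤ 300 iterations. Initialization is
deterministic — evenly spaced quantiles of the *distinct* intensities, so
a heavily populated background cannot collapse two initial centroids; a
random-initialization mode exists and is the only use of the seed here.
A voxel exactly on a centroid receives membership 1 for that cluster.

Marrow is identified structurally rather than by cluster intensity: the
darkest-cluster voxels form the cortical shell and the background; the
connected components not touching the image border are candidate shells,
the one closest to the image center that actually encloses an interior is
taken, and marrow is the hole-filled largest component of that interior
(shell excluded). Misclassified speckles inside the shell are thereby
captured as marrow, which makes the mask robust to noise. Subcutaneous
fat is the largest connected component of the brightest cluster. Hole
filling is applied to the marrow mask only: filling the subcutaneous
annulus would flood its enclosed region (muscle, bone and marrow) and
destroy the ring, so the ring keeps its topology.

If no non-border dark component encloses an interior, segmentation fails
loudly with the slice index.

## Fat/water quantification

Per slice, mean fat- and water-channel signals over marrow voxels give
FF = 100·SI_fat/(SI_fat + SI_water). This ratio is scale invariant, lies
in [0, 100], and is undefined only when both means are zero (an error).
Fat area is (FF/100)·marrow area. Aggregate BMFF is the unweighted mean
of per-slice FF — mirroring the threshold procedure, which reports the
average per-image fraction — with an area-weighted alternative behind a
flag; the default is documented in output headers. Mask transfer between
channels is the identity for co-registered grids; for real data an
integer-pixel in-plane translation can be estimated by phase correlation
between mean slices of the two channels.

## T1 threshold quantification

The threshold is calibrated per slice against the subcutaneous-fat
reference: candidate thresholds are every distinct intensity inside an
annulus bounding the subcutaneous ring (centroid-centered, 1-pixel pad),
so the exhaustive search is guaranteed to find the minimizer of
|area(voxels ≥ threshold) − reference area|; ties resolve to the lowest
threshold, and voxels exactly at the threshold count as fat. Restricting
the search support to the bounding annulus keeps deep-muscle voxels from
satisfying the area match. Calibration is per image because coil shading
varies along the bone; a pooled single-threshold mode exists. Thresholds
are calibrated on the raw (unfiltered) T1 slices.

On marrow whose voxels all share one intensity a single threshold can
only return 0% or 100% — this degeneracy is a property of the procedure,
asserted in the tests, and is why graded recovery is exercised with
speckled phantoms (below). The per-slice fat fraction is fat area over
marrow area; volumes aggregate exactly as in the fat/water procedure.

## The phantom generator

Phantoms emulate a midtibia cross-section as concentric compartments
(outer radii in cm: marrow 0.7, cortical shell 1.1, muscle 2.6,
subcutaneous fat 3.4, skin 3.7) on a 160-pixel grid at 0.05 cm/pixel,
with 24 slices of 0.5 cm thickness and 0.5 cm gap by default; cohort
sampling varies marrow radius (0.5–0.8 cm), fat fraction (0.70–0.90) and
stack length (24–34 slices) between phantoms. A voxel belongs to the
innermost compartment covering its center (no anti-aliasing), so
ground-truth areas are exact pixel counts; pixel-counted areas converge
to the analytic disk areas as spacing shrinks, which is tested at two
resolutions.

Signals are arbitrary units chosen once for plausible T1-weighted
contrast (fat 200 > muscle 120 > skin 80 ≈ red marrow 70 > cortical 20 ≈
background 10) and a fat/water pair in which the marrow mixture satisfies
fat/(fat + water) = FF exactly before noise (fat and red marrow both
total 200 across the pair). Subcutaneous fat and marrow fat share the
same nominal T1 intensity — fat is fat regardless of depot — which is
what makes threshold calibration on the subcutaneous ring transferable to
marrow.

Marrow microstructure has two modes. Homogeneous (default): every marrow
voxel mixes fat and red-marrow signals at the nominal FF; the fat/water
procedure is exact here and the T1 procedure is degenerate by design.
Speckled: on the T1 channel each marrow voxel is drawn Bernoulli(FF) as
pure fat or pure red marrow, emulating the partial-volume speckle a
threshold count actually sees; the realized per-slice speckle fraction is
recorded. The fat/water channels keep the homogeneous mixture in both
modes: a chemical-shift decomposition measures the compartment's mean fat
content either way, and pure zero-signal voxels would otherwise acquire a
Rayleigh noise floor (mean σ√(π/2)) that no real decomposed image
exhibits, biasing the ratio several points low.

Noise is Rician — Gaussian perturbations on two quadrature components
followed by a magnitude — with σ defaulting to 10 (5% of the fat
signal); a clipped-Gaussian mode exists for high-SNR checks. All
randomness flows from a single integer seed; identical configs reproduce
stacks bit-exactly.

What the phantoms do **not** model: coil bias fields, k-space artifacts,
motion, chemical-shift displacement, multi-peak fat spectra, anatomy
beyond concentric cross-sections, or a second bone. Recovery results on
phantoms therefore validate the arithmetic and the segmentation logic,
not robustness to those real-data effects.

## Agreement statistics

Differences are first argument minus second (T1 − IDEAL). The SD of the
differences uses the n−1 denominator, and the Bland–Altman limits are
mean ± 2·SD (not 1.96). Cohen's d uses the equal-weight pooled SD
√((s₁² + s₂²)/2), which equals the (n−1)-weighted pooled SD at equal
group sizes and reproduces the published participant-table effect sizes
to three decimals. The normality gate is Shapiro–Wilk at α = 0.05 per
group; failures (or a constant group, where the test is undefined) fall
to the two-sided Mann–Whitney test — normal approximation with tie
correction for group sizes ≥ 8, exact otherwise; two identical constant
groups return p = 1 by convention. The sample-size helper is the
standard normal approximation n = ⌈2(z_{1−α/2} + z_{power})²/d²⌉ for a
two-sided two-sample comparison; it is a planning aid, not a
reproduction of any published power computation.

Pearson r is reported as NaN with a warning when either input has zero
variance; a zero-variance difference vector yields an undefined paired t
(NaN) when the mean difference is also zero.

## Numerical and I/O choices

- FCM centroids are sorted ascending after convergence so cluster 0 is
  always the darkest; the objective is non-increasing across iterations
  (a tested invariant).
- Geometry is never guessed: NIfTI files written by the package store
  thickness and gap in the header description and the axial zoom as their
  sum; files lacking the annotation are read with gap 0 and a warning.
  DICOM `SpacingBetweenSlices` is treated as center-to-center, so
  gap = spacing − thickness (clamped at zero with a warning).
- All tabular outputs are CSV with units in column names and a leading
  `# config_hash=` comment, making reruns byte-comparable.
- Problem sizes in the validation suite — 160-pixel grids, 20-phantom
  recovery batches, a 15-phantom agreement cohort, 2000 null simulations
  for test calibration — were chosen so that Monte-Carlo error is well
  inside the tolerances being checked while a full run stays around a
  minute on one core.

## Known limitations

- The threshold procedure's accuracy on real scans depends on the
  subcutaneous ring sharing the marrow-fat signal level; bias fields that
  differentially shade the two depots violate this and are not simulated.
- Registration supports integer-pixel translation only; rotation and
  scaling between T1 and fat/water acquisitions are out of scope.
- The fuzzy-clustering cluster count (k = 4) suits the five-tissue
  cross-section; scenes with additional tissues (e.g. a second bone)
  need a different k and possibly different shell selection logic.
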