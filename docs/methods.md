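# Methods

This note documents the models implemented in `cortarch`, the assumptions
behind them, the parameters that matter, and the choices made where the
underlying methodology leaves the design open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## GLI images and profiles (`cortarch.gli`)

A GLI image is computed from a binarized cell-body mask by dividing it into
non-overlapping square measuring fields (default 32 µm; configurable) and
storing 100 × the cell-pixel fraction per field. The output image's
resolution equals the field size; `ContourPair.scale` rescales contours
drawn on the source image onto the coarser grid. Trailing rows/columns that
do not fill a complete field are dropped.

Traverses are constructed by placing origins at equal arclength fractions
along the outer contour and connecting each to the point at the same
normalized arclength fraction of the inner contour, as straight segments.
For parallel or concentric contour geometry this is exactly perpendicular to
the local surface and provably non-crossing; for convoluted contours a
pairwise segment-intersection check rejects the construction rather than
silently producing crossing traverses. This matched-arclength scheme was
chosen over a Laplace/streamline relaxation because it is exact in the
geometries the package generates, simple to reason about, and the degenerate
cases it cannot handle (strongly folded ribbons) are outside this package's
scope.

Profiles are sampled at `n_depth` equidistant relative depths (default 101)
by bilinear interpolation, the simplest scheme consistent with 1 µm/px
source data. Coordinates are pixel-centre, 0-based, with contours in pixel
units.

The 10-feature parametrization treats the profile as a frequency
distribution over relative depth 0–1: features 1–5 are the mean amplitude
and the centroid, SD, skewness and (non-excess) kurtosis of that
distribution; features 6–10 are the same five quantities for the absolute
first derivative (amplitude change per unit relative depth, at
depth-interval midpoints). This is the canonical feature set of the
profile-analysis literature, fixed here explicitly so tests are
unambiguous. A flat profile has zero derivative mass; its derivative
moments are defined as 0. An all-zero profile has no centroid and is
rejected.

## Border detection (`cortarch.borders`)

The pooled within-block covariance uses the bias-corrected (ddof = 1)
per-block covariances. With blocks as small as 10 and 10 features, the
pooled estimate can be ill-conditioned; `shrinkage="auto"` shrinks toward
the diagonal only when the pooled degrees of freedom do not exceed the
dimension or the condition number passes 1e8, so the Mahalanobis distance
stays exactly affine-invariant whenever the estimate is well-posed.
Hotelling's T² always uses the unshrunk pooled covariance — the exact F
transformation `F = T²(n−p−1)/(p(n−2)) ~ F(p, n−p−1)` requires it — and
demands `n₁+n₂−2 > p`.

Per block size, the Bonferroni family is the number of admissible block
positions in that distance function; this is the most direct reading of a
per-section multiple-comparison correction and is exposed through `alpha`.
Local maxima are strict (plateaus take the centre index, ties to the lower
index). Significant maxima are merged across block sizes when within
±`stability_window` profiles (default 2) and kept when supported by at
least `stability_fraction` (default 0.5) of the block sizes 10–24; both
thresholds are configurable because the underlying methodology prescribes
stability "over a large block-size interval" without a number.
Cross-section confirmation matches candidates greedily by nearest position
within a tolerance (default 3 profiles) and requires at least 3 consecutive
sections; the confirmed position is the median of the matched positions.

## Densitometry (`cortarch.quant`)

Calibration fits the saturating film response `grey = g₀ + a(1 − e^{−cR})`
to the co-exposed standards and keeps it only when it reproduces them to
numerical precision; otherwise it falls back to monotone piecewise-cubic
(PCHIP) interpolation, which is exact on linear standards. Films that
darken with dose are handled by working on 255 − grey internally. At least
3 strictly monotone standards are required. Pixels outside the calibration
domain are clamped and counted, and the count is returned so saturated
films are visible downstream.

The grey → R → C_b chain is linear in R and strictly increasing in K_D at
fixed L. The counting constants E, B, W_b, S_a and the dissociation
constant K_D are configuration inputs — they depend on the counter, film
batch and ligand and are not part of the published record; the free ligand
concentrations L ship as a packaged fixture for 13 of the 14 receptors (the
dopamine ligand's protocol row is absent from the published table, so its L
must be supplied).

Area mean densities average, over traverses, the depth-averaged profile
value (trapezoidal rule over relative depth). For receptor profiles the
outer contour follows the pial surface rather than the layer I/II
interface. Where the original densitometric chain left the aggregation
order unspecified, this package averages profiles per section, then
sections, then hemispheres.

## Three-level statistics (`cortarch.stats`)

The data model is `D_arh = α₀ + α₁A_a + α₂R_r + α₃A_aR_r + β₁H_h + ε` with
Gaussian hemisphere intercepts and residuals. Because the design is a
balanced crossed layout with one observation per (area, receptor,
hemisphere) cell, the exact test of any fixed-effect term in the
random-intercept model coincides with the F-test of the ordinary blocked
ANOVA in which hemisphere enters as a blocking factor. `cortarch` uses that
exact F by default (`method="anova"`); the ML likelihood-ratio comparison
of the mixed model with and without the interaction is available as
`method="lrt"` but is anticonservative at small simulation sizes (a
generic small-sample property of the chi-square approximation), which is
why it is not the default. A REML `MixedLM` fit backs effect estimates.

Level 2 tests the area effect per receptor and applies Benjamini–Hochberg
FDR over the receptor family; level 3 tests all C(n,2) unordered area
pairs within a receptor as contrasts of the blocked per-receptor model,
with BH-FDR at the full pair family per receptor (528 for 33 areas; the
family size is a parameter). Levels 2 and 3 are gated on the preceding
level being significant; `require_gate=False` overrides the gate for
simulations. Simulation-based checks of calibration and power run at
5 areas × 4 receptors × 4 hemispheres with 200 replicates — the package's
chosen desk-scale study size, at which the calibration and power claims
are size-generic while each replicate fits in milliseconds.

## Multivariate analyses (`cortarch.cluster`)

Fingerprints are z-scored per receptor before any distance computation so
high-density receptor systems do not dominate the Euclidean metric. Ward
linkage runs on the observation matrix (scipy encoding: merge heights are
√(2·ΔESS)); the cophenetic correlation is the Pearson correlation between
input and dendrogram-implied distances, and `linkage_comparison` reports it
for ward/single/complete/average on identical input.

The k-means cluster-count selection is a permutation-calibrated gap
criterion: for each k (with a k = 1 baseline) the log within-cluster
dispersion is compared against its distribution over datasets whose
columns are permuted independently — preserving marginals, destroying
joint structure. k is *acceptable* when every gap increment from 2..k
exceeds z(level)·SE of the permuted gap (level 0.95 by default), and the
selection is the largest acceptable k, or 1 when none is supported. The
defaults are 999 permutations and 100 k-means restarts per fit
(k-means++ seeding, seeded RNG); tests and the demo pipeline use fewer of
both since their planted configurations are insensitive to restart count.
PCA is an SVD of the column-centred matrix; each component's sign is fixed
so its largest-magnitude loading is positive.

## Connectivity (`cortarch.connectivity`)

Subject matrices are demeaned per vertex and concatenated in time; group
inference runs on the concatenated data with no per-subject random
effects, mirroring the single-analysis group design the module implements.
The representative time course of an area is the first principal component
of its (demeaned) vertex courses — covariance PCA by default, with a
correlation-PCA option — sign-aligned to correlate positively with the
area's mean course, since the component's sign is otherwise arbitrary.
Correlations are clipped at |r| ≤ 1 − 1e−7 before the Fisher transform so
z stays finite at r = ±1; zero-variance targets are flagged and excluded
from summaries rather than silently set to 0.

The area registry pairs the 35 delineated prefrontal areas with 76
non-prefrontal target areas by region (16 premotor, 15 cingulate,
6 somatosensory, 23 parietal, 16 occipital; 111 in total). The
non-prefrontal labels are synthetic placeholders — the registry carries
counts and region assignments, not the prior parcellations' names.

## Synthetic data (`cortarch.synthetic`)

Every generator is a pure function of its spec, including a mandatory seed
(no global RNG state). Ribbons render one laminar mean curve per segment
into image columns with i.i.d. Gaussian pixel noise clipped to [0, 255] —
the simplest noise model consistent with 8-bit imaging; the generator does
not attempt cell somata, staining texture or curvature, so passing tests
demonstrate the statistical machinery, not robustness to histological
artefacts. Synthetic autoradiographs invert the densitometric chain through
a known film response and emit co-exposed standards from the same response,
making generate-then-linearize an identity up to calibration-fit tolerance.
Density tables follow the three-level generative model with effect sizes in
residual-SD units (scalars expand to deterministic centred patterns; the
interaction pattern is a ±1 checkerboard, orthogonal to both main effects).
BOLD-like data draw latent area signals through an eigen-factor of the
target block correlation matrix (exact target covariance in expectation,
tolerant of rank-deficient structures) and add i.i.d. vertex noise; defaults
mirror one 250-volume resting-state scan. Realistic hemodynamics, motion or
spatial autocorrelation are out of scope.

## Known limitations

- The traverse construction rejects, rather than resolves, strongly folded
  ribbon geometries.
- The published density table carries means and SDs only; per-hemisphere
  raw densities are not available, so the three-level statistics can be
  validated only on simulated tables, not against the study's printed
  p-values.
- The clustering/PCA reference results of the original study involve 16
  additional motor-area fingerprints that are not published; with only the
  packaged 33-area table, cluster counts and explained-variance fractions
  are not comparable to those reference values, and on this subset Ward
  linkage is not guaranteed to maximize the cophenetic coefficient.
- Real-MRI ingestion and preprocessing (registration, filtering, surface
  resampling) are out of scope; the connectivity module consumes
  already-clean labelled matrices.
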