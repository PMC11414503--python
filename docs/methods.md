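# Methods

This note records the models, numerical choices and limitations behind
`plaquemorph`, in the spirit of a statistical package's methods appendix.

## Segmentation model

Plaque components are defined purely by CT attenuation: non-calcified
(soft) tissue in the closed window [0, 150] HU and calcification in
(150, 1334] HU. The calcified window is open at 150 so the two windows
partition the intensity axis — a voxel at exactly 150 HU counts as
non-calcified. Both windows are configurable per run, reflecting that
acquisition conditions shift the usable thresholds between scans. The
whole-plaque mask is the Boolean union of the two windows; connected
components are taken at 26-connectivity by default (6 and 18 available), so
diagonal voxel bridges merge the way commercial 3D reconstruction tools
behave. Components whose voxel-count volume falls below 1 mm³ are excluded;
the same rule is applied to calcifications. Manual radiologist revision of
masks (used clinically against calcification blooming) is represented by a
no-op hook (`segmentation.revise_mask`); the automated output is the
package's contract, and no blooming correction is attempted.

Separating plaque from the contrast-filled lumen is the one step that
clinical workflows do by hand (per-plaque regions of interest). Here the
phantom's default lumen intensity is 1500 HU, above the calcified window's
upper bound, so windowing alone excludes the lumen; on real data the upper
bound plays the same role whenever lumen contrast is sufficiently dense,
and an ROI box or an axis polyline remains available otherwise.

## Surface reconstruction

Meshes come from marching cubes at isovalue 0.5 on the zero-padded binary
component (padding guarantees closure). Two field-level corrections are
applied, both of which exist because a raw binary isosurface is a biased
estimator:

- **Anti-aliasing.** The binary field is convolved with a Gaussian
  (σ = 1 voxel, configurable; 0 disables). Without it the voxel staircase
  inflates surface area by a resolution-independent ≈ +8 %.
- **Volume calibration.** Gaussian smoothing shifts the 0.5-level surface
  inward by approximately σ² × mean curvature, which costs ~10 % of the
  volume for components of ~2 mm radius. The anti-aliased mesh is therefore
  rescaled uniformly about its centroid so that its enclosed volume equals
  the raw binary-contour volume, which is nearly unbiased at all sizes.

With both corrections, digital spheres across r = 1.8–10 mm and voxel
sizes 0.2–0.4 mm reconstruct with volume errors between −2.5 % and +0.1 %
and area errors between −1.1 % and +0.4 % (computed by the test suite and
`scripts/acceptance.py`). Components too thin to survive the filter
(e.g. a single voxel) fall back to a 4× nearest-neighbour-upsampled
contour approximating the voxel boundary. No mesh-level smoothing is
applied by default because it changes both metrics; a Laplacian option
exists for visual output only. Degenerate faces are removed and vertices
merged at 10⁻⁶ mm before any metric is computed. Volume is the signed
tetrahedron sum (requires watertightness); area is the triangle sum.

## Morphometry

All measurements are in world millimetres, right-handed, honouring the
NIfTI affine; proximal→distal follows the centreline point order, which
the caller fixes in the flow direction (common → internal carotid).

- **Centreline.** A supplied axis polyline is resampled at uniform 0.5 mm
  steps. From a lumen mask, the mask is skeletonized, the longest
  ridge path between the two farthest skeleton nodes extracted
  (double-sweep Dijkstra on the 26-connected skeleton graph, edge weights
  in mm), smoothed by a 5-point moving average, and extended along its end
  tangents to the mask boundary (3D thinning retracts tube ends by about
  one radius). Branched or multi-component masks are rejected with a
  message directing the user to supply an axis.
- **Endpoints and length.** Every mesh vertex is projected to its nearest
  centreline arc-length coordinate; the extreme vertices are the proximal
  and distal ends (ties broken by smallest vertex index), and plaque
  length is their Euclidean chord. An optional refinement that maximizes
  the chord over the 1 % extreme arc-length bands exists for strongly
  oblique plaques; the default is the cheap, reproducible variant.
- **Surface (geodesic) distance.** Shortest path on the mesh edge graph
  augmented with one round of edge-midpoint Steiner points (each triangle
  contributes the 15 pairwise edges among its 3 vertices and 3 midpoints,
  deduplicated across faces), solved with sparse Dijkstra. The approximation
  error is below 2 % on test shapes (0.008 % on the half-cylinder wrap
  oracle) and the result can never undercut the Euclidean chord. An exact
  polyhedral geodesic would be more code for accuracy the downstream
  statistics cannot use.
- **Cross-sections.** At 0.5 mm arc-length steps, the plane through the
  centreline point with normal along the local tangent cuts the mesh;
  section area is the total enclosed area of the intersection polygons and
  the diameter is the maximal chord of the section points (convex hull
  accelerated). The largest section is refined by bounded scalar
  maximization (golden-section style) within ± one step of the discrete
  argmax. The plaque mesh alone is sectioned, not a plaque+lumen composite.
- **Asymmetry.** Upstream/downstream lengths are arc lengths from the
  endpoint projections to the largest section; their ratio is reported
  as upstream/downstream. VSAR = volume/area (mm; r/3 for a sphere).

Invariants verified in the suite: rigid-motion invariance, exact
similarity scaling (volume ×s³, area ×s², lengths ×s, ratio unchanged),
geodesic ≥ chord, isoperimetric inequality area³ ≥ 36π·volume².

## Statistics

- **Power fits.** `y = a·x^b` by least squares in the original scale,
  initialized from log-log OLS, so its R² is directly comparable with the
  linear fit's (the comparison that probes geometric consistency). The
  exponent p-value uses the asymptotic covariance with a t reference on
  n − 2 df; the package does not claim exactness for it, matching common
  reporting practice. Fitting in log space instead would minimize relative
  error and change R² semantics; the original-scale choice is deliberate
  and documented.
- **Labels.** "Significant" is rho (or r) > 0.5 with p < 0.05 and "strong"
  is rho > 0.8 with p < 0.05, both strict — rho = 0.5 exactly is not
  significant. Labels apply to whichever coefficient the analysis
  produces. No multiple-testing correction is applied; the report records
  the number of tests performed.
- **Normality gating.** Shapiro–Wilk for n ≤ 50, else Kolmogorov–Smirnov
  against a normal with moments estimated from the sample. Gated
  descriptives print `mean ± SD` or `median (P25, P75)`; two-group
  comparisons use the t-test only when both groups pass (p > 0.05), else
  the two-sided tie-corrected Mann–Whitney U.
- **Scheirer–Ray–Hare.** Values are replaced by midranks over the whole
  sample; sequential (type-I: A, then B, then A×B) sums of squares are
  computed on the ranks by least squares, and H = SS / (SS_total/(N−1)) is
  referred to χ² with the term's df. Midranks already absorb ties, so no
  further tie-correction factor is applied to the denominator; the
  decomposition satisfies SS_A + SS_B + SS_AB + SS_within = SS_total by
  construction and is oracle-tested against an independent rank-transform
  + ANOVA decomposition. The test is gated on Levene's test (centre =
  mean): homogeneous variance → parametric two-way ANOVA, else SRH.
- **Subject aggregation.** The 12 summary fields follow their definitions
  exactly; a subject with no calcification gets TCV = TCSA = RTVCP =
  RTSACP = 0, and PVSARm is the VSAR of the plaque attaining the maximal
  volume.

## Synthetic data

The phantom emulates the imaging substrate only: plateau intensities
(background −50 HU, soft plaque 75 HU, calcification 600 HU, lumen
1500 HU) with optional additive Gaussian noise (demo phantoms use
5 HU). It deliberately omits CT physics — no partial-volume beyond grid
resolution, no beam hardening, no calcification blooming — so passing
tests demonstrate correctness of the measurement chain, not robustness to
scanner artefacts. Plaques are wall-attached ellipsoids (with embedded
ellipsoidal calcifications) because closed-form volume, exact surface area
via Legendre incomplete elliptic integrals, and support-function extents
give every downstream stage an analytic oracle; real plaques are more
irregular, so absolute agreement with any particular clinical software's
meshes is not claimed — only internal consistency. Overlapping plaques are
rejected rather than merged to keep per-plaque truth unambiguous;
calcification containment is validated by sampling the calcification
surface (512 points), as ellipsoid-in-ellipsoid containment has no
convenient closed form.

The cohort generator draws per-subject plaque counts as 1 + negative
binomial (mean 2.67, shape 1.5 — every subject has at least one plaque)
and per-plaque volumes as LN(5.2, 0.85) mm³, calibrated so the simulated
total-plaque-volume median sits near 443 mm³ with quartiles roughly
297–742 mm³, the scale of a 42-subject carotid cohort. Downstream
geometric parameters follow the allometric relations with multiplicative
log-normal noise (area prefactor 7.0 at exponent 2/3, length prefactor 2.2
at exponent 1/3, geodesic 15 % above length, noise SDs 0.05–0.18); about
55 % of plaques carry calcification occupying ~15 % of plaque volume on
average. Covariates are linked to subject TPV through a Gaussian copula on
rank-based normal scores: for target Spearman ρ_s the latent Pearson
correlation is r = 2·sin(πρ_s/6), so the empirical rank correlation
converges to the target as n grows (verified at n = 2000 within 0.05).
Default covariate targets mirror the magnitudes such cohorts report
(TG 0.50, TC 0.36, FOL −0.33, VB12 0.30; HDL-C/FIB/UA null), with
marginals matched to typical clinical ranges. A requested |ρ_s| = 1 is
rejected as unattainable under a noisy marginal.

## Problem sizes

The shipped tests and the acceptance script use phantoms up to
~100×100×130 voxels at 0.32 mm, a 10 mm ball at 0.2 mm voxels, 100–200
simulation replicates for stochastic checks, and cohorts of 40–42 subjects
(≈ 110 plaques) — the scale of the motivating study — chosen so the whole
verification cycle completes in minutes on a single core while every
tolerance is still binding.

## Known limitations

- Segmentation assumes threshold separability; lumen/plaque HU overlap
  (poor contrast) requires the ROI/axis path.
- The centreline extractor handles a single unbranched tube; bifurcated
  anatomies need a supplied axis polyline.
- The geodesic is an upper bound with ≤ 2 % observed error, not an exact
  polyhedral geodesic.
- The power-fit exponent p-value is asymptotic.
- Cross-section area of strongly non-convex sections counts enclosed
  polygon area including lobes; the diameter is the maximal chord of the
  whole section set, matching the "largest cross-sectional distance"
  reading.
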