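# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `morphorank`.  Notation: `A` cell area (pixels), `P` cell
perimeter, masks are binary grids in row-major order with origin top-left;
all descriptors are dimensionless.

## Input contract and standardization

The pipeline consumes one binarized cell per image.  `standardize`
enforces the canonical geometry every downstream step assumes:
nearest-neighbour resampling to 0.5 µm/pixel (binary masks must stay
binary, so no interpolation), retention of the largest 8-connected
component (smaller fragments are treated as segmentation debris and
warned about), interior hole filling (4-connected background, the
standard dual of 8-connected foreground), and bounding-box centering on a
300×300 field.  A cell whose rescaled bounding box exceeds the field is
an error — silent cropping would corrupt every descriptor.  The operation
is idempotent and area-preserving under pure translation.

## Perimeter estimation

The cell boundary is traced by marching squares at the 0.5 iso-level
(`skimage.measure.find_contours`, diagonal-connected), and the contour
vertices are smoothed with a 3-point circular moving average before
summing edge lengths.  The raw staircase polygon systematically
overestimates smooth boundaries (a digitized disk reads ~6% long, pushing
circularity to 0.94); after smoothing, disks measure within 1.5% of 2πr
and squares within 1% of 4s.  The same estimator is used for the cell in
`convexity = P_cell / P_hull`, while the hull perimeter is the polygon
edge sum of hull vertices (pixel centers), so convexity ≈ 1 for convex
cells and grows with ramification.

## Soma detection

The cell body is found by morphological erosion/reconstruction.  The mask
is eroded with a 3×3 square until one more erosion would empty it; the
survivors are the soma center.  The center is then dilated step by step
with a 3-pixel cross while surfaces are recorded on both sides.  Dilation
step `j` is compared against the erosion surface `K−j` steps before
extinction (the original cell surface standing in once the erosion
sequence is exhausted): the stopping index `i` is the first dilation
whose surface exceeds the matched erosion surface.  At that point the
reconstruction has recovered a body of the same scale as the pre-erosion
soma but has not yet crept far along thin processes (the cross dilation
advances only ~1 px/step down a process).  The image after `i+1` erosions
and the image after `i` dilations are averaged, thresholded at 0.25
(i.e., their union) and clipped to the cell mask.  Dilation surfaces are
measured unconstrained — a geodesic (cell-clipped) dilation would
converge exactly to the whole cell and never cross the reference
surface; the final clip restores the partition invariant
soma ∪ processes = cell, soma ∩ processes = ∅.

Calibration on analytic shapes: a bare disk of any radius partitions with
processes/cell ≈ 0.08 (the crossing lands at city-block radius ≈ 1.25 R,
whose diamond covers all but four caps of the disk), and a 10-px-radius
disk with a 60-px process yields soma ≈ 320 px against the π·10² = 314
ideal, with the distal process fully excluded.  Cells too small to
survive one erosion (< ~9 px) are treated as all-soma with a warning.

## Skeleton, Sholl profile and branching index

The full cell mask is thinned with `skimage.morphology.skeletonize`
(topology-preserving; Euler number unchanged).  Skeleton length counts
skeleton pixels outside the soma.  Endpoints have exactly one 8-neighbour
on the skeleton; branch pixels have three or more, and 8-adjacent branch
pixels are merged and counted once, since raster thinning splits
T-junctions into touching pixel pairs.  Raster thinning is *not* exactly
equivariant under 90° rotation; skeleton-derived descriptors therefore
carry a ~3% reproducibility band in the invariance tests while all other
descriptors match to rounding.

Sholl circles are centered on the soma centroid with a 2-px radial step
up to the cell's maximal extent.  An intersection is one 8-connected run
of (skeleton − soma) pixels inside the annulus [r−1, r+1); counting runs
rather than single-pixel circle crossings is robust to the raster
aliasing of circles.  The branching index is
`Σ_n (I_n − I_{n−1}) · r_n / (300·300)` with `I_0 = 0`, signed successive
differences exactly as defined, radii in pixels.  Because the profile
decays to zero at the largest radii, the sum is typically negative for
ramified cells; its magnitude grows with arbor size, and the ranking
stage is indifferent to the sign convention (standardization plus PCA
absorb any affine, direction-consistent transform).

## Fractal dimension and lacunarity

Box counting uses power-of-two box sizes anchored at the cell's
bounding-box origin, capped at 1/8 of the largest bounding-box dimension
(at least the three smallest sizes 2, 4, 8 are always used).  Boxes
comparable to the object in size only measure near-full cover and drag
the log–log slope down — with the cap, a 200-px line measures 0.96–0.98
and a filled square exactly 2.0.  The dimension is the least-squares
slope of log N(ε) vs log(1/ε).

Lacunarity uses the gliding-box algorithm: for each box size
r ∈ {2,…,64} fitting the bounding box, every r×r window fully inside the
box contributes its foreground mass M; `Λ(r) = Var(M)/Mean(M)² + 1`, and
the reported value is the slope of log Λ vs log r (≤ 0; more negative for
gappier cells).  Window sums are computed with an integral image, so the
cost is linear in the bounding-box area per scale.  If fewer than two box
sizes fit, the value is 0 with a warning.

## Convex hull and coordinate PCA

Hull vertices come from `scipy.spatial.ConvexHull` on foreground pixel
centers; area is evaluated with the shoelace formula and perimeter as the
polygon edge sum.  The span ratio compares the equivalent-ellipse axes of
the hull polygon, computed from the polygon's exact second-order moments
(closed-form contour integrals), and the radii ratio compares extreme
centroid-to-vertex distances.  Collinear cells raise a degenerate-hull
error.

Linearity is `VarMax/VarMin` of the eigenvalues of the pixel-coordinate
covariance (population normalization); axis lengths are 4√eigenvalue and
inertia is their ratio (= √linearity).  A perfectly straight cell has
`VarMin = 0`; the feature assembler substitutes 1/12 — the variance of a
1-px-wide uniform strip — and warns, rather than emitting infinity.

## Ranking

Inversion of the five opposite-direction descriptors is a sign flip of
the raw column: it reverses the ranking direction totally and without
distorting spacing (a reciprocal would fail at 0 and warp intervals).
Standardization is a z-score with population SD; zero-variance columns
are dropped with a warning.  Because all prepared columns have unit
variance, the PCA eigen-decomposition of `XᵀX/n` is a correlation-matrix
PCA.  Eigenvector signs are fixed deterministically (PC1: circularity
loading ≥ 0; PC2: largest-|loading| entry ≥ 0) so weights and phases are
reproducible across platforms.  Parameter projections use the
correlation-circle convention (loading × √eigenvalue); rankings within
PC1 are unaffected by the common √λ₁ factor.

The selection is the shortest |PC1|-ranked prefix whose cumulative
projection share reaches the threshold (default 0.8, configurable).
Weights are `W_n = |w_n|/|w_0|` ∈ (0,1] and phases
`φ_n = arctan(y_n/W_n)` ∈ (−π/2, π/2), with the signed PC2 projection in
the numerator and no quadrant-aware variant.  Andrews curves are sampled
at 360 angles of t ∈ [0,1); θ\* is the grid argmax of across-cell
variance with ties broken toward the smaller angle, verified against a
10× finer brute-force grid.  The score axis has no intrinsic sign, so
scores are oriented to correlate positively with the prepared circularity
column (most amoeboid first); whether a flip was applied is recorded in
the output.

A structural property of this synthesis worth knowing: weights are
positive and phases cannot exceed ±π/2, so a parameter whose prepared
direction *anti-aligns* with PC1 contributes incoherently at the
max-variance angle.  The fixed five-element inversion list homogenizes
directions for typical microglia cohorts but cannot guarantee it for
every dataset; when several strong parameters anti-align, the Andrews
ranking tracks the PC1 ordering more loosely (observed on synthetic
cohorts: PC1 score recovers a known gradient at ρ ≈ 0.93–0.96, the
Andrews score at ρ ≈ 0.84–0.99 depending on the cohort's correlation
structure).

## Synthetic cells

The generator emulates the input contract, not microscopy: single
connected hole-free masks at 0.5 µm/px spanning amoeboid → rod-like →
ramified shapes.  A cell is a filled soma disk (radius 13 → 8 px as the
complexity knob c goes 0 → 1, matching the relatively larger somata of
amoeboid microglia at rodent scale) plus `8c` processes — fractional
counts add one proportionally shorter process so the gradient is smooth —
grown as persistent random walks (step 1 px, heading noise
σ = 0.05 + 0.1c per step, length 15 + 40c px with ±10% jitter, caliber
tapering from ~1.2 px at the base).  Branch counts per process are fixed
at round(3·branch_prob) with branch points at set arc fractions rather
than Bernoulli-per-step: branch-count lottery otherwise dominates
between-cell variance and obscures the gradient.  `rod_bias` concentrates
launch angles around one axis to produce bipolar rod-like cells.  Per-cell
seeds derive from a single cohort seed via `numpy` SeedSequence, so
cohorts are deterministic end to end.

The heading-noise and branching calibration targets the generator's
stated contract: the measured ramification index must track the
generative complexity at Spearman ≥ 0.9 for a 100-cell cohort, which
holds with margin (0.93–0.96 across cohort seeds).  What passing tests on
this substrate do *not* show: robustness to segmentation noise, touching
cells, staining artifacts, or anisotropic imaging — the generator draws
ideal binary masks by construction.

## Problem sizes and defaults

Synthetic validation uses 100-cell cohorts on the 300×300 field — large
enough for stable rank statistics and PCA, small enough that a full
measure-and-rank pass completes in seconds.  Defaults: resolution
0.5 µm/px, field 300×300, selection threshold 0.8, 360-angle grid; all
recorded in every run report for reproducibility.

## Known limitations

- 2-D only; descriptors quantify projected silhouettes, not 3-D arbors.
- No process-hierarchy reconstruction; the skeleton is summarized by
  counts and length only.
- The soma partition includes proximal process stubs within the
  reconstruction radius for heavily ramified cells; descriptors using the
  soma are calibrated against this behaviour, not against a manual soma
  outline.
- The thinning result, and hence skeleton-derived descriptors, can differ
  by a few percent from other thinning implementations.
- The overlap coefficient is a shared-bin histogram estimator; different
  binning rules give slightly different percentages.
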