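# Methods

This note documents the models, algorithms and defaults implemented in
`morphomcia`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## From label volumes to meshes

Binary organ masks are cleaned **per axial slice** (not in 3-D):
morphological opening then closing with a 5×5 box kernel, then filling
of enclosed background regions. Slice-wise processing removes
slice-plane artifacts and interior structures (ducts, bronchi) without
bridging anatomy across slices. The open–close composition is an
alternating filter and is idempotent in practice; a property test
checks this on random volumes. Note that opening annihilates any
structure thinner than 5 voxels in-plane — objects of interest must be
larger than the kernel.

Surfaces come from marching cubes at iso-level 0.5 (the standard choice
for a binary field) on a zero-padded volume, so masks touching the
array border still yield closed surfaces; vertex coordinates are in mm
via the voxel spacing. Only the connected surface component with the
largest face count is kept ("largest isosurface"). Paired organs
(lungs, kidneys) are split by connected component; sides are assigned
by centroid along the first axis with *smaller coordinate = right*
(radiological convention), with a `flip` flag for datasets with other
orientations. Meshes with ≠ 2 components are refused rather than cut:
fused kidneys are a data problem, not something to resolve silently.

Meshes are then decimated to a common vertex budget (default 1000,
tolerance ±2%) with an in-package quadric edge-collapse decimator.
Collapses violating the manifold link condition or flipping adjacent
faces are rejected, so genus-0 inputs keep Euler characteristic 2 and
stay watertight. Taubin smoothing (λ = 0.5, μ = −0.53, 10 passes — the
classic low-shrink parameters) suppresses marching-cubes staircase
noise; a test verifies < 1% mean-radius change on a sphere. Finally
vertices are mean-centered.

## Registration

Each organ family is registered to a template: the mesh whose
divergence-theorem volume is closest to the cohort median (ties → the
lowest index, with a 1e-9 relative tolerance so float noise cannot
override the rule).

Alignment is two-step **coherent point drift**: the source vertex set
is treated as centroids of an isotropic Gaussian mixture fitted to the
target by EM — first with an affine transform, then with a non-rigid
displacement field expanded in a Gaussian kernel over the source points
(width β = 2, regularization λ = 2 — the original CPD defaults; both
configurable). Inside the solver both sets are centered and scaled by
the target RMS radius, and results are mapped back, so registration is
invariant to pre-translation. The EM iteration is deterministic
(identity initialization, no randomness); the mixture negative
log-likelihood is non-increasing across iterations (tested). Stopping:
relative NLL change < 1e-5 or 100 iterations; non-convergence returns
the best iterate with a warning rather than failing.

Vertex correspondence between the moved source and the template is the
exact minimum-cost bijection under Euclidean distance
(`scipy.optimize.linear_sum_assignment`). Vertex counts are forced
equal at decimation time so the assignment problem is square and the
correspondence a bijection. Features are computed on the **moved**
geometry in template vertex order: curvature must be comparable
vertex-wise, which requires the registered shape, not the original
pose. Correspondence uses the non-rigidly moved coordinates for the
same reason. Both choices are recorded in the transform log.

## Shape features

Per registered mesh, one column with d = V + P + 1 entries:

- **Mean curvature** per vertex, from the cotangent-Laplacian
  mean-curvature normal with barycentric vertex areas, H = ‖Δv‖/2.
  Sign convention: positive where the curvature normal agrees with the
  inward vertex normal, i.e. convex regions positive (a unit sphere
  averages +1, verified to 5% at 1000 vertices). Vertices touching
  zero-area triangles get the neighborhood average, with a warning.
- **Euclidean/geodesic distance ratios** at P = 500 seeded random
  landmark pairs (distinct, uniform without replacement, one fixed set
  per organ family). Geodesics are Dijkstra shortest paths on the edge
  graph with Euclidean weights — a deterministic upper bound on the
  exact polyhedral geodesic, adequate at this mesh resolution (an
  antipodal pair on a fine unit sphere measures π to within ~6%, so
  the sphere's ratio lands near 2/π). Ratios lie in (0, 1] by the
  metric inequality; values near 1 mean locally straight geometry,
  small values mean curved or folded geometry.
- **Surface-area-to-volume ratio** (requires watertightness; 3/r for a
  sphere, tested at 2%).

Standardization centers each feature row and scales to unit
**population** variance (divisor n, not n−1), so the total inertia with
uniform weights equals the retained feature count exactly — keeping the
inertia identities exact rather than off by (n−1)/n. Zero-variance rows
(e.g. a distance ratio that equals 1 for every individual because the
pair is joined by a straight edge chain) are dropped with a warning.

## Dimension reduction

Inertia and co-inertia are implemented from their summation forms
(I_X = Σᵢ wᵢ‖xᵢ‖²_Q; co-inertia = ‖Q^½ X W Y′ R^½‖²_F with X, Y
features × samples) and tested against brute-force double sums.

**MCIA.** Per axis, maximize Σ_s Cov²_W(X_s′u_s, h) subject to
‖u_s‖ = 1 and h′Wh = 1. Writing z = W^½h, the optimum is the top
eigenvector of K = Σ_s W^½ X_s′ X_s W^½, with u_s ∝ X_s W h and the
block's squared covariance ‖X_s W h‖² its *pseudo-eigenvalue* (they sum
to the axis eigenvalue — asserted to 1e-10). Later axes: every block is
deflated by its component along h under the W inner product, making the
h axes mutually W-orthogonal. Implementation decisions:

- **Block pre-scaling**: after standardization each block is divided by
  the square root of its total inertia (`block_scaling="unit_inertia"`),
  so an organ cannot dominate the objective merely by having more
  features; set `"none"` to disable.
- **Weights** w_i = 1/n and identity feature metrics (features are
  already standardized).
- **Block scores** per axis are the deflated block's projection onto
  u_s, rescaled to unit W-variance, so all organs are comparable in the
  common plot and consecutive axes carry non-redundant structure.
- The **synthetic center** of an individual is the across-organ mean of
  its block scores, rescaled to unit W-variance per axis. This
  definition makes identical blocks produce coincident scores and
  centers (zero line lengths — maximal between-organ correlation), and
  line length shrinks as between-organ correlation grows.
- **Axis signs** are fixed by making the largest-magnitude loading
  entry positive, for reproducible plots.
- `variance_explained` is the axis eigenvalue over trace(K) of the
  undeflated problem.

The per-individual spread statistic sums, over organs, the 2-D distance
from the organ's score to the synthetic center; it is rotation-
invariant in the plane.

**PCA** is an SVD of the centered block (scores = VΣ), sign-fixed like
MCIA. **t-SNE** wraps scikit-learn's exact-gradient implementation
(default perplexity min(30, ⌊(n−1)/3⌋), 1000 iterations, early
exaggeration 12, PCA initialization, fixed seed), deterministic given
the seed; a test checks the final KL divergence against an independent
re-implementation of the objective.

## Bagplots and robustness

Tukey halfspace depth is computed **exactly**: the count of points in a
closed halfplane through p changes only at normals orthogonal to some
p→data direction, so evaluating all critical angles plus interval
midpoints is exhaustive. (Cohorts here are tens to hundreds of points;
no approximation is needed.) An O(n³)-style brute-force oracle backs
this in the tests, along with affine equivariance of the depth values.

The **bag** interpolates between the tightest depth contour holding
≥ ⌊n/2⌋ points and the next-deeper contour. Interpolation is the
Minkowski combination λ·outer ⊕ (1−λ)·inner (computed as the hull of
pairwise vertex combinations — exact for convex polygons), which nests
monotonically in λ; λ is then bisected so that **exactly ⌊n/2⌋ points
are inside** (boundary-inclusive) for data in general position. The
depth median is the centroid of the maximal-depth region; the fence is
the bag inflated by ρ = 3 about the depth median (the classic bagplot
default; configurable). Points on a polygon boundary belong to the
inner region — a deterministic tie rule. Collinear data are refused
with a suggestion to jitter.

The **location-robustness statistic** is, per individual and method,
the maximum number of organs assigned the same region; with S organs it
is always ≥ ⌈S/3⌉ by pigeonhole. Methods are compared with a
tie-corrected Kruskal–Wallis test and pairwise two-sided Mann–Whitney-U
tests: exact null distribution when both groups have ≤ 20 observations
(scipy's exact method, which ignores ties — still closer to the
enumeration null than the normal approximation at these sizes), normal
approximation with tie correction otherwise. Degenerate comparisons
(all values identical) report H = 0, p = 1 rather than erroring. Raw
and Holm-adjusted p-values are both reported, since no particular
multiplicity correction is canonical here.

## Synthetic cohorts

The generator emulates the study design — n individuals × S organ
families with correlated shape variation — not organ anatomy. Every
mesh is a star-shaped surface over one shared Fibonacci-lattice sphere
triangulation (exactly `n_vertices` vertices, watertight):
r(u) = R_ellipsoid(u) · (1 + Σ_k a_k B_k(u)), with six fixed degree-2/3
polynomial basis functions B_k (each scaled to max 1). Coefficients mix
the individual's latent factors z_i (default 2 factors, standard
normal) through a fixed mixing pattern and an organ loading, plus
independent noise:

a_{i,s} = amplitude · (loading_s · P z_i + σ_d ε),  ε ~ N(0, I).

Defaults: 30 individuals, 3 organs with distinct ellipsoid radii,
amplitude 0.02 (typical radial modulation a few percent — comparable to
smooth inter-individual organ-shape variability), σ_d = 0.3 (so organs
correlate strongly but not perfectly through the latent factors),
latent_dim = 2 with a pattern whose first column dominates. Planted
outliers multiply one individual's (one organ's, or all organs')
coefficient vector by κ; the generator refuses parameter combinations
driving the radius factor ≤ 0.05 ("deformation too large"). Everything
is bit-reproducible from the seed.

Because all meshes share one sphere parameterization they are in exact
vertex correspondence by construction. The pipeline therefore offers
`register=False` to skip CPD for such data; the repeated-cohort
end-to-end experiments use this fast path (registering 60 already-
corresponding meshes per cohort adds nothing to what the registration
recovery tests establish), while the pipeline smoke test runs the full
CPD + Hungarian chain.

**What passing these experiments shows — and doesn't.** Latent-factor
recovery (first MCIA axis correlating |r| ≥ 0.9 with the first planted
factor when loadings are equal and σ_d is small) and whole-individual
outlier recovery (κ = 5 outlier landing in the outlier region in at
least half its organs, in ≥ 18 of 20 seeds) demonstrate that the
feature → MCIA → bagplot chain transmits correlated shape signal and
flags gross whole-individual anomalies at realistic cohort sizes. They
do **not** establish performance on real CT organs: real segmentations
have non-star-shaped geometry, registration residuals that leak into
curvature features, imaging-protocol batch effects, and outliers far
subtler than a 5× amplitude multiplier.

## Problem sizes and numerics

Default experiment sizes were chosen to keep a full analysis at desk
scale: cohorts of 30 individuals × 3 organs at 1000 vertices and 500
landmark pairs run the feature/MCIA/bagplot chain in seconds per
cohort; CPD registration (the dominant cost, O(V²) per EM iteration) is
exercised on 300-point sets and 300-vertex cohort smokes. Numerical
tolerances that matter: CPD stops at 1e-5 relative NLL change; MCIA
treats eigenvalues below 1e-12 of total inertia as rank deficiency and
returns fewer axes with a warning; the bag's bisection runs 60 halvings
(interval < 1e-18); point-in-polygon uses a 1e-9 distance tolerance for
boundary inclusion.

## Known limitations

- Slice-wise morphology assumes the scan's axial resolution is the
  natural cleanup plane; strongly anisotropic spacings may warrant 3-D
  morphology, which is deliberately not offered.
- Hungarian correspondence is O(V³); fine for 10³ vertices, not for raw
  marching-cubes meshes — decimate first.
- Graph geodesics overestimate true surface geodesics by a
  triangulation-dependent few percent; ratios are comparable across a
  cohort sharing a mesh budget but are not exact differential-geometric
  quantities.
- MCIA here standardizes once and applies unit-inertia block scaling;
  other MCIA implementations apply their own internal transforms, so
  coordinates match other software only up to such conventions.
- Bagplot fence factor ρ = 3 is a convention, not an estimated
  threshold; with very heavy-tailed score distributions the outlier
  region is conservative.
- Orientation harmonization across a dataset (mirroring) is a config
  flag, not automatic.
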