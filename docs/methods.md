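# Methods

This note documents the models and procedures implemented in `fmtensor`,
the parameter choices that matter, what the phantoms do and do not emulate,
and the numerical conventions a user relying on the outputs should know.

## Geometry conventions

Volumes are stored with array axes (x, y, z); the physical coordinate of
voxel (i, j, k) is `origin + index * spacing` (voxel-centre convention,
0-based, µm). TIFF stacks are read page-by-page as z-slices and transposed
into this order. All public APIs — window sizes, strides, step lengths,
radii — speak physical µm, so anisotropic acquisitions (e.g. 1.2 µm in
plane, 4 µm between planes) are handled by the spacing alone.

## Skeletonization and graph extraction

Binary masks are thinned with Lee-style 3D medial-axis erosion
(`skimage.morphology.skeletonize`, method `"lee"`). Skeleton voxels are
classified by their number of 26-neighbours on the skeleton: endpoints
(<2, isolated voxels included), slabs (=2), junctions (>2). Thinning can
leave several mutually adjacent junction voxels; all 26-connected clusters
of endpoint/junction voxels are merged into a single graph node at the
cluster centroid (the behaviour users of the common skeleton-analysis
plugins expect). Edges are traced through slab-voxel chains; the edge
length is the sum of µm steps along the voxel path, terminal node voxels
included, honouring anisotropic spacing — not the Euclidean node-to-node
distance, which would understate tortuous vessels. Two special cases:
an isolated voxel becomes an edgeless endpoint node, and a closed cycle of
slab voxels (no node voxel anywhere on it) receives one inserted
junction-class node carrying a self-edge, so that every slab voxel belongs
to exactly one edge path.

No spur pruning is applied by default; `prune_graph` (and
`--prune-below`) removes terminal branches below a length threshold when
the segmentation is noisy.

Voxel-path lengths on 26-connected grids overestimate oblique straight
lines by up to ~8% (a zig-zag path at 30° to an axis); the tube-phantom
validation bounds the combined thinning + tracing length error at 10%.

The baseline segmenter (`binarize_baseline`: global threshold plus
removal of small 26-connected components) exists so the pipeline is
self-contained; the framework is agnostic to how masks are produced, and
externally segmented masks are first-class inputs. Segmentation quality is
quantified with the Dice coefficient (1.0 for two empty masks, by
convention).

## Descriptors

*Vascular*: one descriptor per graph edge — the straight chord between the
two node positions, anchored at their average. The chord, not the curved
slab path, is the orientation that the tensor statistics should see; for
very tortuous vessels the analysis window (90 µm) is large relative to the
inter-node spacing, so chord error is secondary.

*Cellular*: per label, the second central moment matrix of the voxel
physical coordinates is diagonalized; the descriptor is the principal
eigenvector scaled by 2·√(5·λ₁). For a solid ellipsoid the coordinate
variance along a semi-axis a is a²/5, so this magnitude is the cell's long
diameter — only the direction and relative magnitude matter downstream.
Cells whose two leading eigenvalues are within 5% relative spread
((λ₁−λ₂)/λ₁ < 0.05) have no stable axis (near-spheres); they are excluded
from orientation statistics but counted, so density statistics stay
honest. Labels below 20 voxels are skipped as unreliable moment estimates.
Pooled cell axes are unweighted by elongation; an elongation weighting
would emphasize the most anisotropic cells and is easy to add upstream of
`compute_tensor_field` by scaling the vectors.

## The covariance tensor field

Descriptors are pooled into cubic windows of side W (default 90 µm) on a
regular grid of centres with stride s (default 20 µm) — a mesoscale
comparable to diffusion-MRI voxels, large enough to smooth the fields.
Window membership is decided by the midpoint only, half-open on the high
side (c−W/2 ≤ m < c+W/2 per axis): a segment spanning a boundary belongs
to exactly one window and is never double counted. The centre grid starts
at the descriptor bounding-box minimum and extends by `ceil(extent/s)+1`
centres per axis so the bbox maximum is still covered.

Each member contributes its two endpoints ±vector/2; the pooled cloud has
mean exactly zero by construction, and the tensor is the population
covariance over the 2N endpoints, CM = (1/2N)·Σ p pᵀ. A sample-variance
variant (2N−1) is available by flag. Windows with fewer than `min_count`
(default 2) descriptors are flagged invalid: a single segment yields a
rank-1 tensor whose "dispersion" is meaningless, and weighting voxels by
their element count is what gives the maps statistical significance.
Low-count masking is the default; DEC maps can alternatively weight
colours continuously by count.

Eigendecomposition sorts λ₁ ≥ λ₂ ≥ λ₃, clamps round-off negatives in
[−1e-9, 0) to zero, and sign-normalizes each eigenvector so its
largest-magnitude component is nonnegative — eigenvectors are axial and
the sign carries no information, but a fixed convention makes outputs
reproducible. Exactly degenerate eigenvalues fall back to the solver's
deterministic ordering; tests never assert eigenvector identity under
ties.

## Scalar and colour metrics

FA and the Westin coefficients use the standard diffusion-tensor forms.
The Westin triple is sum-normalized — cl = (λ₁−λ₂)/Σλ, cp = 2(λ₂−λ₃)/Σλ,
cs = 3λ₃/Σλ — so the three indices partition 1 at every valid voxel, a
property the tests exploit; the λ₁-normalized variant is available by
flag. DEC maps use RGB = |v| components (X red, Y green, Z blue),
optionally weighted by FA or by normalized count.

## Wall frame and transmural profile

The anatomical wall frame is an idealized cylinder: the user supplies a
long-axis point and direction plus the epicardial (outer) and endocardial
(inner) radii. Per window centre: r̂ is the outward radial, l̂ the long
axis, ĉ = l̂ × r̂, and the transmural depth d = (R_epi − r)/(R_epi − R_endo)
clipped to [0, 1] runs from epicardium (0) to endocardium (1). Centres on
the axis have no frame and are invalid. Arbitrary wall meshes are out of
scope; for a mid-ventricular short-axis analysis the cylinder is the
standard first approximation, and it is the geometry the phantoms realize
exactly.

The helix angle is computed after axially normalizing v₁ so its
circumferential component is nonnegative: HA = atan2(v·l̂, v·ĉ) in
(−90°, 90°], TA = elevation out of the tangent plane. v₁ ∥ r̂ has no
defined HA (NaN) and TA = ±90°.

Profiles aggregate HA per depth bin with the axial circular mean
(double-angle embedding); the reported per-bin median is the plain median
and is only meaningful away from the ±90° wrap. The transmural span is
HA(0) − HA(1) from a Theil–Sen fit of HA against depth over all retained
centres; for fields with more than 2000 valid centres the fit uses an
evenly spaced depth-ordered subsample of 2000 (Theil–Sen is quadratic in
memory; 2000 points estimate a 1-parameter slope with negligible extra
variance). Because HA is treated linearly here, laws spanning beyond ±90°
would wrap and need unwrapping first — a known limitation.

**Edge-window exclusion.** A window whose cube protrudes past the epi- or
endocardial surface samples depth one-sidedly: its segment population has
mean depth up to (W/2)/T·span away from the window-centre depth (T = wall
thickness), which for W = 90 µm and T = 260 µm would bias edge bins by
more than 10°. When the window size is passed to `transmural_profile`,
centres whose sampling cube is not fully inside the wall annulus are
excluded (cube radial maximum bounded exactly at the corners, the minimum
conservatively toward the axis). If the wall is thinner than the window no
centre qualifies and the filter is skipped entirely — the profile then
carries the full edge bias and its span is attenuated, which is the honest
answer for a wall the window cannot resolve.

## Tractography

Tracking integrates the chosen eigenvector field (v₁ by default; v₂/v₃
interrogate sheet-like organization) with a 2nd-order Runge–Kutta
(midpoint) scheme: direction at x (sign-aligned with the previous heading,
because the field is axial), half step, direction at the midpoint, full
step. The single termination criterion is a propagation angle above
`max_angle` (default 35° — far above the per-voxel turning of smooth
fibre fields, but required to follow a branching vascular continuum);
tracks also stop at the field boundary, at invalid (low-count) windows,
and at a `max_points` safety cap (default 10 000 per direction). No
anisotropy threshold is applied. Seeding defaults to every valid window
centre; tracking is bidirectional and the two half-tracks are concatenated
at the seed. The seed direction's axial sign is canonicalized so a global
sign flip of the field reproduces byte-identical tracks.

Direction lookup is nearest-valid-centre by default — the most literal
reading of voxel-by-voxel propagation; trilinear interpolation with
per-corner sign correction is available and is what the curvature
validation uses (a 50 µm circular field is followed for a full revolution
with radial drift below 0.01%, comfortably inside the RK2 error budget).
The integration step defaults to half the grid stride (10 µm at the
default 20 µm stride), a standard stability choice for deterministic
tracking. Display subsampling keeps a seeded uniform 15% of tracks by
convention; no length filter is applied unless requested.

Determinism is a design contract throughout: fixed inputs and parameters
give hash-identical GraphML/NRRD/trk artifacts across runs.

## Phantoms: what they emulate, and what they do not

*Helical shell* — a cylindrical wall (defaults: inner radius 120 µm, outer
380 µm, height 300 µm) whose local fibre direction follows a transmural
helix-angle law, by default linear from +60° at the epicardium to −60° at
the endocardium (a 120° span; murine hearts are reported somewhat larger).
Segment midpoints are uniform in the shell (density 1e-4 µm⁻³ ≈ 55
segments per 90 µm window, comfortably above the 5-per-window validity
floor), vectors are 15 µm long with a 5° angular jitter and random axial
sign. The defaults were chosen once so that per-window statistics, not
luck, determine the validation outcome.

*Cell population* — non-overlapping solid ellipsoids (semi-axes 10, 4, 4
µm, i.e. elongated cell bodies) with principal axes drawn from an axial
Watson distribution about a mean orientation, concentration κ = 300
(≈ 2.3° angular spread; κ = ∞ degenerates to perfect alignment, κ = 0 to
isotropy). Overlaps are rejected, not merged, so per-cell moment ground
truth stays exact. The Watson sampler uses an exponential-envelope
rejection scheme with ≈ 50% acceptance at any κ.

*Tube rasterization* — voxels within a radius of any centreline segment;
requires the radius to be at least one voxel on the finest axis.

The phantoms emulate geometry and orientation statistics only. They do not
simulate the microscope: no point-spread function, no shot noise, no
staining heterogeneity, no segmentation errors (only optional thresholding
of a clean mask). Passing the phantom validations therefore demonstrates
the correctness of the *analysis* — skeleton topology, covariance
statistics, angle conventions, integration geometry — not robustness to
imperfect segmentation, which is governed by the upstream segmenter and
quantified separately via the Dice metric.

## Validation problem sizes

The shipped validation studies (tests and `scripts/acceptance.py`) run at
desk scale, chosen to exercise every code path with comfortable
statistics: 100 random descriptor sets (≤500 descriptors) against an
exact-arithmetic (fsum) brute-force covariance oracle; three tube
topologies (straight/Y/H) rasterized at 1 µm; the helical shell with
~12 000 segments over ~21 000 windows; 50 voxelized cells; a one-revolution
circular-orbit RK2 check at 0.5 µm steps; and a doubled end-to-end pipeline
run on a reduced shell (outer radius 110 µm, 2 µm voxels) for bit-level
determinism.

## Known limitations

- The wall model is a cylinder; apex and strongly curved regions need a
  mesh-based frame that is out of scope here.
- Helix-angle profiling assumes the law stays within (−90°, 90°].
- Chord descriptors understate orientation variation along highly
  tortuous branches; subdividing long edges before descriptor extraction
  is the workaround.
- Tracking operates in eigenvector space (per-window eigendecomposition,
  then interpolation); interpolating the tensor itself and
  re-diagonalizing would be a possible extension.
- Lee thinning is not exactly equivariant under axis permutation of the
  raw mask (scan-order effects); the graph stage is, given the same
  skeleton.
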