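# fmtensor

Orientation tensor imaging of fluorescence microscopy volumes: skeleton
graphs, sliding-window covariance tensor fields, anisotropy and
helix-angle maps, and deterministic streamline tractography.

## The problem

Optically cleared, whole-organ fluorescence datasets (e.g. the lectin-stained
murine cardiac microvasculature, or GFP-labelled tissue-resident macrophage
populations) are far too dense to interpret structure-by-structure. What a
tissue biologist usually wants from them is *organization*: the locally
prevailing orientation of the vascular bed or of a cell population, how
anisotropic that organization is, and how it varies across the organ — for
the heart, the classic helical rotation of fibre orientation across the
ventricular wall.

`fmtensor` answers those questions the way diffusion-tensor MRI answers them
for water diffusion, but starting from **segmented microscopy data** instead
of diffusion measurements:

1. **Descriptors.** A binarized volume is reduced to oriented feature
   descriptors **r**ᵢ: for vasculature, the mask is thinned to a unit-width
   medial-axis skeleton, classified into endpoint / slab / junction voxels by
   their 26-neighbour count (<2 / =2 / >2), converted to a node-branch graph,
   and each inter-node segment becomes one descriptor. For cell populations,
   each labelled cell contributes the principal axis of its best-fitting
   ellipsoid (from the second central moments of its voxels, semi-axis
   a = √(5·λ)).

2. **Tensor field.** A cubic sampling window ε (default **90 µm**, stride
   **20 µm**) slides over the volume. Descriptors whose midpoint falls in a
   window contribute their two extreme points ±**r**ᵢ/2 to a zero-mean point
   cloud, whose 3×3 variance–covariance matrix

   CM = (1 / 2N) Σₖ **p**ₖ **p**ₖᵀ   (µm², N descriptors, 2N endpoints)

   is the window's tensor. Each window also records N, used to weight or
   mask statistically weak voxels.

3. **Eigen-metrics.** The eigen-system λ₁≥λ₂≥λ₃, v₁,v₂,v₃ of CM gives the
   standard-deviation ellipsoid: v₁ is the locally prevailing orientation,
   √λᵢ the ellipsoid radii. Derived maps: fractional anisotropy
   FA = √(3/2)·√Σ(λᵢ−λ̄)² / √Σλᵢ², Westin linear/planar/spherical shape
   coefficients (sum-normalized, cl+cp+cs = 1), directionally encoded colour
   (RGB = |v| components; X red, Y green, Z blue), and glyph/vector-field
   exports.

4. **Wall-frame angles.** Against a cylindrical wall model (user-supplied
   long axis and epi/endo radii), v₁ is decomposed into a helix angle HA
   (signed angle from the circumferential direction within the wall-tangent
   plane, axial, in (−90°, 90°]) and a transverse angle (elevation out of
   that plane), and HA is profiled against transmural depth.

5. **Tractography.** Deterministic 2nd-order Runge–Kutta tracking through
   the (axial) eigenvector field, seeded from all valid windows,
   bidirectional, with a single termination criterion: a propagation angle
   greater than 35°. No FA threshold is applied; typically only 15% of the
   tracks are displayed.

Phantom generators supply ground-truth inputs at desk scale: tubular
networks whose direction follows a prescribed transmural helix-angle law,
rasterized to masks, and populations of voxelized ellipsoidal cells with
Watson-distributed axes — so every stage is validated against analytic
truth.

## Worked example

```python
import numpy as np
import fmtensor as fm

# synthetic helical-shell microvasculature: ±60° linear helix-angle law
spec = fm.HelicalShellSpec()
segments, truth = fm.make_segment_cloud("helical_shell", spec, seed=1)
print(f"{len(segments)} vascular segment descriptors")

field = fm.compute_tensor_field(segments, window=90.0, stride=20.0, min_count=2)
print(f"{int(field.valid.sum())} valid windows "
      f"(median {int(np.median(field.counts[field.valid]))} segments/window)")

eigen = fm.eigendecompose(field)
fa = fm.fractional_anisotropy(eigen)
print(f"median FA = {np.nanmedian(fa.values):.3f}")

frame = fm.build_wall_frame(eigen, (0, 0, 0), (0, 0, 1),
                            spec.outer_radius, spec.inner_radius)
ha, ta = fm.helix_transverse_angles(eigen, frame)
profile = fm.transmural_profile(ha, frame, n_bins=10, window=field.window)
print(f"transmural helix-angle span = {profile.span_deg:.1f} deg")

tracks = fm.track(eigen, index=1, step=10.0, max_angle=35.0, max_points=500)
shown = fm.subsample(tracks, 0.15, seed=1)
print(f"{len(tracks)} streamlines tracked, {len(shown)} displayed")
```

prints

```
12252 vascular segment descriptors
20906 valid windows (median 55 segments/window)
median FA = 0.974
transmural helix-angle span = 120.6 deg
20906 streamlines tracked, 3136 displayed
```

The high median FA says the phantom's segments are strongly aligned within
each 90 µm window (they follow one local fibre direction with only 5° of
jitter); the fitted transmural span recovers the phantom's ±60° law to
half a degree. Real masks enter the same way via
`read_volume` → `binarize_baseline` → `skeletonize` → `build_graph`.

The `fmtensor` CLI wraps the same stages
(`fmtensor run --out DIR --seed 1` runs phantom → mask → skeleton → graph →
descriptors → tensor → metrics → tracks and writes
`mask.tif, skel.tif, graph.graphml, descriptors.csv, tensor.nrrd, fa.tif,
dec.png, profile.csv, tracks.trk` plus the config and a run log).
Streamlines are written as TrackVis `.trk` (identity orientation,
corner-origin voxel-mm convention, µm read as mm), tensors as 4D NRRD
(components xx, xy, xz, yy, yz, zz in µm², then the count N; stride as grid
spacing, window size in the header), glyphs as legacy ASCII VTK polydata.

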