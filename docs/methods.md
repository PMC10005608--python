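# Methods

This note records the models, conventions, parameter choices and known
limitations behind `grainct`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

Arrays are indexed `(z, y, x)`. In the canonical grain frame, z is the
longitudinal axis (vertical), y the lobe axis, and x runs ventral → dorsal,
so the crease lies on the −x side. Cross-sections are XY planes. Indices are
0-based; extents use the inclusive voxel span (a single voxel has extent 1).
Rigid transforms act as `p_out = R (p_in − c_in) + c_out + t` with `c` the
geometric grid centres; Euler angles are reported in the intrinsic Z–Y–X
convention, but all internal math uses matrices.

## Intensity calibration

Raw 32-bit beamline dumps are mapped linearly onto [0, 255] between the
`clip_percentile` and `1 − clip_percentile` quantiles (default 0.001 for
real data, to absorb hot pixels; 0 in tests), with clamping outside and
half-away-from-zero rounding. A constant input maps to zero. The mapping is
monotone and idempotent on already-calibrated data.

## Segmentation

Threshold (Otsu by default; a manual 8-bit value can be supplied) →
morphological opening (ball, radius 2) → keep the largest connected
component touching at most one volume face → binary reconstruction of that
component inside the thresholded foreground (restores hairs and thin detail
the opening removed) → closing (ball, radius 3) → 3D hole filling.
Components touching ≥ 2 faces are the mounting tube and tapes, which always
enter from outside the field of view. Connectivity is 26 for components and
6 for hole filling. The radii are the smallest that removed the phantom's
tape and hair bridges while preserving the shell.

Consequence worth knowing: the closing fills the narrowest part of the
crease, so the mask slightly overfills the crease tip (a few voxels). This
biases the per-slice crease-tip trace a constant ~4 voxels dorsally (which
cancels in the line fit and does not affect alignment) and contributes a
small porosity excess in the crease-adjacent columns (below).

## Alignment

1. Per slice, the crease tip is the contour vertex farthest from the convex
   hull boundary (deepest convexity defect), kept when the defect depth is
   ≥ 5 voxels; ties break toward smaller x.
2. The crease axis is the first principal component of the tip cloud, with
   one robust refit after dropping the 10 % worst residuals (top and bottom
   slices are atypical where the lobes merge). The minimal rotation takes it
   to +z.
3. The in-plane rotation about z aligns the major principal axis of the
   second moments of the central 50 % of slices with y; the crease side is
   forced to −x (180° flip if needed).
4. The centroid is translated to the image centre, **rounded to whole
   voxels**. Sub-voxel centring has no downstream benefit (heights are
   binned into 50 rows, extents are voxel counts) but forces an extra
   interpolation of the grayscale. That matters: a residual sub-voxel shift
   makes trilinear resampling blend void (≈0) and shell (≈190) intensities,
   and a blend fraction of only 50/190 ≈ 0.26 pushes a tissue pixel under
   the fixed 140 threshold, inflating measured porosity by up to ~0.1 on a
   finely voided phantom.

Grayscale volumes are resampled with trilinear interpolation, masks with
nearest-neighbour, both by inverse mapping with zero fill.

## Morphometry

`clean_mask` = opening with ball(3) (hair removal) + 3D hole filling (void
filling); extents are inclusive voxel spans × voxel size; volume is the
voxel count × voxel volume. The surface-pore counter finds connected
below-100 patches with 5–300 voxels on the 2-voxel-deep outer shell of the
ventral half. It is heuristic screening plumbing: on grains with a porous
shell it also fires on voids that graze the surface crust, so it is meant
for solid-shell (early-stage) material; no claim of biological stoma
identity is made.

## Ventral pericarp porosity

Per aligned slice: contour of the mask (marching squares at the 0.5 level,
followed by shrinkage-free Taubin smoothing, 10 iterations of ±(0.5/−0.53)
Laplacian steps — raw marching squares inflates a disc perimeter by ~6 %,
Taubin brings it to ~1 % while changing a square's area by ~0.1 %) →
resampling to 1 px arclength and circular moving average (window 7) → the
arc between the two hull touch points bracketing the deepest defect (depth
≥ 5), split at the tip → 10 equal-arclength sub-curves per half → band
regions between each sub-curve and its inward parallel at the stage depth →
fraction of covered pixel centres with value < 140.

- Column order: −10…−1 on the −y side (crease-adjacent last), +1…+10 on the
  +y side (crease-adjacent first). Row 0 is the grain bottom.
- The height bin of slice z is `floor(50·(z − z_min)/(z_max − z_min + 1))`.
- Cells with no covered pixels are missing (NaN), never 0 — 0 is a valid
  porosity. Cross-grain averaging is cell-wise over present values.
- Offset depths per stage default to {50: 25, 100: 20, 150: 15, 200: 12,
  250: 10} voxels. These are plausible pericarp depths, exposed in the
  config; no published values exist. The depth must not exceed the local
  pericarp thickness, or the bands sample the seed interior, whose mid-gray
  level also falls below 140.
- Inward normals are decided per region by testing an offset probe against
  the contour polygon; offset bands that self-intersect at tight curvature
  are repaired by clipping the loops (logged as a per-table summary).
- The bands include the intact epicarp layer — no attempt is made to peel
  it — so measured porosity underestimates the mesocarp value by roughly
  the crust-to-depth ratio.

**Crease-tip artifact.** A moving average applied across a sharp V-shaped
concavity displaces the contour toward the chord, i.e. across the air gap,
so the innermost (±1, sometimes ±2) columns pick up a few dark gap pixels.
On a void-free phantom with a perfectly sharp V this bounds at ≈ 0.03–0.05
in those columns while every other column stays below 0.02. Real creases
are smooth at pixel scale, where the effect is smaller, but values in the
crease-adjacent columns should be read with this bias in mind.

## Mesh cropping (serial-contour stitching)

Between two consecutive closed contours, the stitching is the minimum-total-
triangle-area acceptable triangulation: a monotone path on the (m+1)×(n+1)
correspondence grid, dynamic programming per starting correspondence, all n
starts tried (the per-row scan uses a cumulative-sum trick so each DP is a
sequence of O(n) vector operations). End contours are capped with centroid
fans — correct for the star-shaped contours this tool is used on, a
documented limitation otherwise — and the global winding is fixed by the
sign of the enclosed volume (signed tetrahedra).

Inside/outside voxel classification casts a ray along +x per voxel centre
and counts parity. Ray origins carry a fixed tiny irrational jitter
(~1e−5·√2, √3, √5 per axis), so exact vertex/edge hits cannot occur and
boxes behave half-open: a cube spanning [2, 10)³ contains exactly 8³ voxel
centres.

## Oriented crop

The local z axis is the mean gradient of the Gaussian-smoothed intensity
(σ = radius/3) over the query ball, normalized; it points from dark
(outside) to bright (tissue). x is completed in the plane spanned by the
global x axis and the new z (global y as fallback when nearly parallel), y
closes the right-handed frame. Output voxels sample the source at
`center + R·offset` with trilinear interpolation and zero fill.

## The phantom

The synthetic grain is the union of two prolate ellipsoids (lobes offset
±0.38·a_y along y, each with semi-axes (a_z, 0.62·a_y, a_x)) minus a ventral
V-wedge whose tip locus is a vertical line — so the canonical phantom's
crease axis is exactly +z, and the body is rolled so its centroid sits at
the grid centre. The pericarp shell is the inward Euclidean-distance band
(default 12 voxels); the interior models the seed. Default 8-bit levels are
(0, 90, 190, 250) for background/interior/shell/tape with Gaussian noise
σ = 8 — chosen so both Otsu and the fixed 140 threshold are meaningful.

Voids are random spheres (radius 2–4) carved in the ventral shell band
underneath a sealed one-voxel surface crust, rejection-sampled without
overlap until the target band fraction is met; when random non-overlapping
packing saturates (random sphere packing stalls near ~0.38, while fractions
up to 0.5 must be reachable), overlap is allowed for the remaining draws.
The truth record carries the brute-force band fraction and a 50×2
height-by-side breakdown. Stomata are radius-1.5 channels carved from the
ventral surface through the crust into a radius-3 internal air chamber;
hairs are thin bright polylines on the top; the tape is a bright slab on a
volume border, kept clear of the grain so that binary reconstruction cannot
re-merge it; an optional concentric ring artefact and the noise complete the
image. All randomness flows from the spec seed.

What the phantom does **not** emulate: phase-contrast fringes, cellular
texture inside tissues, partial-volume gradients at real interfaces, the
narrow slot-like crease of older grains (its V is sharp and open), beam
hardening. Passing tests therefore demonstrate geometric and algorithmic
correctness of the pipeline, not robustness to every real-beamline
artefact.

## Problem sizes and numerical choices

The validation suite runs phantoms at 160³ (porosity recovery, alignment
recovery) and 112³ (unit tests, determinism), sizes at which every stage's
behaviour is already asymptotic while the whole suite stays fast. Porosity
recovery is checked at void fractions 0.1/0.3/0.5 with three replicates;
alignment recovery over twelve misalignments with Euler angles up to 30°.
The synthetic misalign–realign round trip resamples the mask twice, so
absolute extents can drift one voxel per pass (+1 typical); extents are
invariant within ±1 voxel across the misalignment grid.

Degenerate inputs are rejected with messages rather than guessed at: empty
or constant volumes, convex contours (no crease), fewer than three usable
crease slices, open meshes, zero-gradient orientation queries, infeasible
phantom geometry (shell thicker than a lobe radius).

## Known limitations

- Porosity near the crease carries the smoothing artifact described above.
- Tissue-level (multi-class) segmentation is out of scope; the mask is the
  whole caryopsis.
- The stitcher handles one contour per slice (no branching topologies) and
  centroid-fan caps assume star-shaped end contours.
- The pore counter is a screening heuristic, confounded by surface-grazing
  shell voids.
- Stage-dependent offset depths are configurable defaults, not calibrated
  anatomical measurements.
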