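# Methods

This note documents the models, conventions and numerical choices behind
`voxscene`, in the spirit of a methods section: what is computed, under
which assumptions, and where the deliberate design decisions lie.

## Coordinates and calibration

A volume is a grid of 8- or 16-bit intensities with calibration
`(cx, cy, cz)` — the physical extent of one voxel in µm — and a physical
origin. Voxel indices are 0-based and a voxel's physical **center** is
`origin + (i + 0.5) · calibration` per axis, so projections and cropping
behave symmetrically about the grid. Internally the voxel array is stored
in `(z, y, x)` plane order, matching multi-page TIFF layout; the public
API indexes by `(x, y, z)`.

Stacks are read and written as multi-page grayscale TIFF via `tifffile`.
Calibration is persisted in the resolution tags (x/y) and ImageJ-style
`spacing` metadata (z); a file without calibration loads as (1, 1, 1) µm
with a logged warning. Mixed page sizes/depths and RGB pages are rejected.

## The scene and its view chain

A scene owns a viewport (pixels), a background color, a registry of
uniquely named contents, and a global view chain applied in the fixed
order **zoom ∘ rotation ∘ pan** (pan first). Each increment composes onto
its own component as `new = increment ∘ old`; for the scalar zoom and the
additive pan the order is immaterial, and for rotations the convention is
frozen by a matrix-oracle property test. Viewer coordinates are re-centered
on the viewport center, and pixel `(i, j)` covers viewer coordinates
`(i + 0.5, j + 0.5)`; with an identity view, 1 µm maps to 1 px.

`reset_view` clears the chain, pans the union bounding box of the visible
contents to the viewer origin, and sets the zoom so the box's larger
projected extent fills 90% of the shorter viewport side.

Contents auto-name as `<Kind>-<n>`. New contents are visible, opaque and
white; orthoslice contents start at the volume mid-planes `floor(n/2)`.
An invisible content contributes nothing to any render, and toggling
visibility off and back on restores renders bitwise.

## Rendering

All rendering is orthographic software rendering (no GPU, no perspective
camera). The camera looks along +z of viewer space; smaller viewer z is
closer.

**Transfer function.** Opacity is proportional to intensity —
`α(i) = (i / i_max) · (1 − content_transparency)` — so dark voxels are
more transparent than bright ones, `α(0) = 0`, and α is monotone
non-decreasing. Color is the gray ramp modulated by the content color;
both maps can be overridden per call site.

**Volume rendering.** One ray per pixel through the composed
(viewport ∘ view ∘ local) transform, trilinearly sampled at a fixed step
and composited front-to-back with the *over* operator
(`C += (1−A)·α·c`, `A += (1−A)·α`) with early termination at
`A ≥ 0.999`. The reference sampling step is half the smallest calibrated
voxel extent; other steps apply the opacity correction
`α' = 1 − (1 − α)^{Δ'/Δ}` so the composite is consistent across sampling
rates. Samples outside the grid read zero (transparent). For a
homogeneous medium the composite obeys the closed form
`A = 1 − (1 − α)^N`, which the tests check to 1e-6. Multiple volume
contents are composited sequentially rather than with interleaved
depth-sorted sampling — a deliberate simplification adequate for
non-overlapping contents.

**Orthoslices.** The three planes `x = ix`, `y = iy`, `z = iz` are drawn
as textured quads with nearest-voxel lookup (crisp slices), depth-ordered
against the shared z-buffer. Planes seen edge-on project to a line and
are skipped. Under an identity view the z-plane reproduces the voxel
slice pixel-for-pixel, which the tests use as an array-slice oracle.

**Meshes.** Flat-shaded two-sided Lambert rasterization with a headlight
(light along the view direction): per-face shade
`0.15 + 0.85·|n·ẑ|/‖n‖`; the small ambient floor keeps grazing faces
distinguishable from the background. Triangles are drawn back-to-front
with a z-buffer; transparent fragments blend with *over* and do not write
depth. Point meshes and landmark spheres are drawn as screen-space disks
(landmark radius in µm scaled by the view zoom).

**Snapshots** compose all of the above: meshes, orthoslices and landmarks
share a z-buffer, then volume renderings are composited over the result.
PNG output is 8-bit RGBA.

## Isosurfaces

Isosurface extraction uses marching cubes (via scikit-image's
topologically consistent Lewiner variant) with vertices placed on cube
edges by linear interpolation and scaled by the calibration. Because
intensities are integral, "voxels equal to the threshold count as inside"
is implemented by placing the iso-level at `threshold − 0.5`. The volume
is padded with a below-level constant before extraction so bright regions
touching the border are capped and the surface stays closed.

Binary masks — the typical segmentation input — produce staircase
surfaces whose raw triangle area systematically overestimates the true
boundary (about 9% for a radius-20 binary sphere) even though enclosed
volume is nearly unbiased. Extraction therefore ends with
volume-preserving Taubin smoothing (λ = 0.5, ν = 0.53, 10 iterations, the
`trimesh` convention), which leaves topology untouched and reduces the
sphere-area bias to ~2% while perturbing enclosed volume by < 0.1%. Pass
`smoothing_iterations=0` for the raw triangulation.

Mesh area is the sum of triangle areas; enclosed volume is the absolute
sum of signed origin-tetrahedra and requires a closed, consistently
oriented mesh (checked via edge counts; open meshes raise). Mesh files
round-trip through ASCII OBJ/PLY (order- and connectivity-exact) and
binary STL (coincident vertices merge on import, as the format stores
loose triangles).

## Volume editing and 3D cropping

Voxel edits go through `set_voxel`/`crop_with_roi`, which emit a change
notification exactly once per mutating call; renderers and cached
isosurfaces subscribe to refresh themselves. Cropping projects every
voxel center through a caller-supplied composite view transform
(orthographic: z dropped) and fills those inside the polygon. Membership
uses the even-odd rule with the boundary counting as inside — chosen over
any-overlap membership for determinism and exhaustivity of testing; the
tests compare against a brute-force point-in-polygon oracle (shapely)
over every voxel center. A crop that changes no values (e.g. repeating
the same crop) reports 0 and emits no event.

## Landmarks and rigid registration

Landmarks are named, colored points in content-local calibrated
coordinates with a display radius (µm; radius is a viewing property and
is not persisted). Files are plain CSV `name,x,y,z,r,g,b` with positions
in µm and colors in [0, 1]; malformed rows raise a parse error carrying
the line number.

Registration pairs landmarks across two sets by identical names
(homonymous pairing; unpaired names are ignored with a warning) and fits
the least-squares rigid transform via the cross-covariance SVD with the
reflection case corrected to det(R) = +1. At least 3 non-collinear source
points are required. The model is strictly rotation + translation; an
isotropic-scale (similarity/Umeyama) variant is available behind the
`with_scale=True` flag. On noiseless synthetic pairs the recovery error
is at machine precision (tests assert < 1e-9), and the planar case agrees
with a 0.001°-grid brute-force angle search.

Resampling pulls each output voxel center back through the inverse
transform and samples the source trilinearly (`scipy.ndimage`,
`grid-constant` boundary handling so exact-grid samples at the border are
not lost to floating-point noise); outside samples read 0. An identity
transform reproduces the input bitwise; integer-voxel translations shift
exactly; ±90° rotations about a grid axis equal array permutations.

## 4D playback and animation recording

A time series is an eagerly loaded, ordered list of volumes sharing dims
and calibration. Playback controls clamp at the ends (optional looping);
edits and annotations require the paused state and touch only the current
frame, each frame owning its own landmark set.

`record_rotation` renders one frame per angular step about the
scene-vertical axis (default step 2°, i.e. 180 frames; configurable, the
step must divide 360). The pre-recording view state is saved and restored
verbatim, so the recording leaves the scene bitwise-unchanged rather than
relying on 360° of floating-point increments to cancel. Transform-event
recording captures exactly one rendered frame per zoom/rotate/pan/local-
transform change between `start_recording` and `stop_recording`. Frame
stacks save as multi-page RGB TIFF; video encoding is out of scope.

## Synthetic data generators

The fixtures emulate the study inputs without any external data: a binary
sphere phantom (voxel inside iff its center is within the radius), bead
fields as unions of small spheres with ground-truth centers returned for
registration tests, a stochastic 26-neighbor lattice growth simulation
(tips step with directional persistence, branch with probability
`branch_prob`, default 0.1, writing maximal intensity; frames are
cumulative, so bright sets are nested over time), and paired landmark
sets related by a known rigid motion plus optional isotropic Gaussian
noise. All generators are pure functions of their arguments including the
RNG seed.

What they do **not** emulate: real point-spread functions, shot noise,
intensity inhomogeneity, anisotropic artifacts, or deformable motion.
Passing tests therefore demonstrate the correctness of the geometry,
rendering and registration machinery on idealized data, not robustness to
real acquisition noise.

## Problem sizes and tolerances

The test suite and the acceptance script run on deliberately small
inputs: ≤ 48³ phantoms for isosurface metrics, ≤ 128² viewports for
rendering, ≤ 32³ exhaustive cropping oracles, 10-landmark registrations.
These sizes were chosen so each check's expected behavior is computable
by an independent oracle (closed form, brute force, or permutation) while
the whole suite completes in seconds; the algorithms themselves have no
size-specific assumptions. Key tolerances: compositing closed form 1e-6;
rigid recovery 1e-9; sphere area within 5% and volume within 2% of the
analytic values at r = 20; resampling round trip MAE < 2% of dynamic
range on smooth phantoms; mesh vertex round trips 1e-6.

## Known limitations

- Orthographic projection only; no perspective camera.
- Sequential (not depth-interleaved) compositing of multiple overlapping
  volume contents.
- Transparent mesh fragments do not write depth, so intersecting
  transparent surfaces resolve by draw order, not exact depth.
- STL import merges coincident vertices (format limitation).
- Interactive windows, GUIs and video codecs are explicitly out of scope;
  the CLI and the Python API are the interfaces.
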