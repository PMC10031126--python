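# Methods

This note records the model behind `sthcube`, the conventions and numerical
choices the implementation commits to, what the synthetic embryo does and
does not emulate, and the known limitations.

## Data model

A recording is a `TemporalDataset`: contiguous integer frames 0..T−1, each
holding a set of labeled objects. Object ids are positive integers; 0 is
reserved for background everywhere, which is what lets the projected volume
double as a label image. Geometry is either a closed, orientable triangle
mesh per object (the usual output of segmentation + meshing pipelines) or a
shared labeled voxel grid per frame.

The `LineageTree` assigns each id an inclusive life interval
[t_birth, t_last] and at most one parent; a division is two children whose
t_birth is strictly after the parent's t_last. Frames are integers because
segmentation is per-frame; inclusive intervals match that. Selection
propagation (used by highlight/hide tracking) maps a seed (id, t) to the
seed's id plus all ids reachable through child edges. Ancestors are
deliberately not affected: tracking answers "what does this cell become",
and pulling in ancestors would make hiding a late cell erase its whole
history. `validate_lineage` cross-checks a dataset against a tree and
reports every disagreement rather than raising, so inconsistent external
data can be audited; the tree constructor itself enforces the
parent-before-child invariant unless explicitly built in non-strict mode
for exactly that auditing purpose.

Annotations are a long table (property, id, t) → value; scalar values keep
whatever unit they were computed in (the generator emits cell volume in
cubic world units and remaining lifespan in frames).

## Projection

The cutting plane is a point, a unit normal and an in-plane "up" vector;
"up" is Gram–Schmidt-orthogonalized against the normal and the in-plane
basis is u = up × normal, v = up, making (u, v, normal) right-handed.
`median_plane` offers a data-driven default: the total-least-squares plane
through the centroids of every (object, time) instance — the plane that
keeps the population closest to the cross-section over the whole recording,
which is the natural starting cut for an embryo.

One orthographic frame is fitted for the entire recording: the (u, v)
rectangle is the union over all frames of the cross-section's bounding
rectangle, expanded by `margin_fraction` (default 0.02) per side and padded
symmetrically so pixels are exactly square. A single shared frame is the
point of the construction — refitting per frame would shift slices relative
to each other and destroy the stacking alignment. Because the
parameterization is a rigid in-plane coordinate system, pixel distances
times the pixel size equal world distances exactly (no spatial distortion).

The slab half-thickness ε controls how much geometry around the plane a
cross-section captures. ε is exposed as a user parameter and defaults to
one pixel's world size; since the pixel size itself depends on the fitted
bounds, the default is resolved by a first bounding pass with a
zero-thickness slab. Rasterization has two first-class modes:

* **membrane** (default): a pixel gets an object's id when the object's
  surface passes within max(ε, half the pixel diagonal) of the pixel
  center. Surface distance is computed by exact vectorized point-triangle
  distance against the triangles intersecting the slab. This is the right
  mode for hollow surface-mesh datasets, where a cross-section shows cell
  membranes, and it is monotone in ε by construction.
* **filled**: a pixel gets the id when its center lies inside the closed
  mesh, decided by an even-odd crossing count of the in-plane ray against
  the mesh's plane section (an unordered segment soup works for parity, so
  no curve stitching is needed). Non-watertight meshes are skipped with a
  warning — parity is meaningless for them.

Contested pixels go to the smallest id: deterministic and independent of
iteration order. Labeled voxel inputs are sampled at pixel centers by
nearest neighbor in both modes; labels are nominal and must never be
interpolated.

Slices are stacked into the `STCVolume` grid indexed (v-row, u-column,
time). The default resolution is 256×256 in-plane with one slice per frame.
In STC voxel coordinates — used by cuts, the renderer, the light and
queries — voxel (i, j, k) has its center at (i, j, k), in (u, v, time)
order.

## Shading and rendering

Normals are precomputed once per volume, because they depend only on
occupancy: the binary occupancy (id ≠ 0) is smoothed with a Gaussian of
σ = 1 voxel (on by default; it suppresses stair-step artifacts of the
binary field) and differentiated with the separable 3×3×3 Sobel-Feldman
kernel along each axis, with edge replication at the borders. Ids are
nominal labels, so the occupancy — never the id values — is what gets
differentiated. Normals point from object into background (against the
occupancy gradient); voxels with vanishing gradient store the zero vector
and receive only ambient shading.

The value lookup maps (id, t) to a color: numeric properties are clamped
and normalized over [vmin, vmax] (auto min/max unless given) and pushed
through a matplotlib colormap; categorical properties go through a stable
hashed palette (CRC32 of the label into tab20), so colors are identical
across runs and processes. Missing entries render as sentinel gray —
an unannotated cell should be visibly "unknown", not invisibly dropped.

Rendering is opaque first-hit raycasting: one orthographic ray per pixel
(orthographic by default because perspective foreshortening along the time
axis reads as a false size trend; a perspective camera is not offered),
marched in 0.5-voxel steps from the volume entry point; the first voxel
that is occupied, unfiltered and on the kept side of the active cut
terminates the ray. The shaded color is

    ka·C + kd·max(N·L, 0)·C + ks·max(N·H, 0)^s

with C the lookup color (overridden to solid red for highlighted ids — an
override, not a tint, so tracked lineages cannot be confused with any
colormap value), L the direction to the point light, H the half vector, and
defaults ka = 0.2, kd = 0.7, ks = 0.3, s = 16 — an unremarkable matte
material with a slight sheen; all configurable, with a guard against
ka + kd > 1.2 that can be explicitly overridden. The light has no distance
attenuation and moving it can never change which voxel a pixel shows.

Cuts zero the voxels strictly on the discarded side of a plane given in
voxel coordinates (centers exactly on the plane are kept): a normal along
the time axis scrubs time, an in-plane normal extracts the evolution of a
line segment, and oblique cuts follow slowly drifting objects. The stored
volume is immutable; cuts and filters return new volumes or masks, which is
what makes switching them cheap.

## Filters

One `FilterState` drives every view. The value filter suppresses an (id, t)
instance when its mapped value is defined and outside [lo, hi]; instances
with missing values are kept (and shown as sentinel gray) — silently hiding
unannotated cells would bias exploration. The time filter keeps a window of
slices and clamps the preview cursor (`current_time`) into it. The object
filter cycles normal → highlighted → hidden and applies the new state to
the seed's full descendant closure across all time instances. Filters
materialize as a boolean keep-mask that is the exact conjunction of the
three individual masks, and rendering a filtered volume is pixel-identical
to rendering the pre-masked volume — filtering commutes with rendering.

## The synthetic embryo

The generator emulates the statistical structure of a cleavage-stage
embryo recording after segmentation: n cells packed in a fixed ellipsoid
envelope (semi-axes 90 × 75 × 65 world units, think micrometres), total
cell volume roughly conserved so radii shrink by 2^(−1/3) per division,
small per-frame centroid jitter (magnitude |N(0, σ)|, default σ well below
a cell radius, matching recordings where inter-frame motion is far smaller
than cell size), synchronous division every p frames with optional
asynchronous cells that skip exactly one round (cycle 2p), and an optional
radial "cavity" displacement ramping up after an onset frame as a crude
stand-in for gastrulation-like deformation. Cells are icospheres
(subdivision 2) with a fixed 2% per-vertex radial perturbation drawn from
the cell id, so shapes are stable over time, no two cells are congruent,
and daughter volumes sum to the parent's within mesh-noise tolerance.
Daughters are placed ±half a daughter radius from the parent center along a
random axis — the pair separates by one daughter radius in total and stays
adjacent/overlapping, as abutting sister cells do in real segmentations;
overlap resolution is the rasterizer's tie-break. Every random draw flows
from the single seed, so identical parameters give bit-identical output.

Default parameters (8 initial cells, 20 frames, period 8, jitter 1.0) give
a desk-scale recording: large enough to show waves and tracking, small
enough that the full pipeline runs in seconds. Tests and the acceptance
script use smaller variants (1–2 roots, 10–20 frames, 48–128 px frames)
for the same reason; the properties they check are resolution-independent.

What the generator does **not** emulate: cell mechanics and adhesion,
non-convex cell shapes, membrane contact geometry (real neighbors share
walls; these spheres merely overlap), unequal divisions, apoptosis or
migration. Tests passing on this data therefore validate the projection,
rendering, filtering and lineage machinery — not any biological claim about
real embryos, where segmentation errors, irregular shapes and stronger
motions add failure modes the synthetic data cannot produce.

## Numerical choices and degenerate inputs

* Tie-breaks: smallest id wins a contested pixel; voxel centers exactly on
  a cut plane are kept.
* Gradient normalization threshold 1e−12; normals below it are zero.
* The even-odd parity test uses the half-open crossing rule, so shared
  segment endpoints are never double counted; pixel centers sit at
  half-integer offsets, making exact edge grazing a measure-zero event.
* The raycaster samples at fixed 0.5-voxel steps with nearest-voxel
  lookup; along axis-aligned views this visits voxels in exactly the
  monotone order an arbitrarily fine marcher would.
* Empty intersections fail loudly: fitting a frame when no geometry meets
  the slab at any frame is an error, not an empty volume.
* Writers are deterministic (no timestamps in payloads); NRRD support is a
  minimal raw-encoding little-endian codec, which is the only subset the
  package writes.

## Limitations

* One shared plane for all frames: objects drifting across the plane can
  appear to shrink or vanish in the STC even though they merely moved —
  the classic projection artifact; `median_plane` mitigates but cannot
  remove it. Per-frame plane tracking is out of scope.
* Opaque rendering shows exactly one object per pixel; interior structure
  behind the first hit is invisible by design (use cuts and filters to
  reveal it). Semi-transparent transfer functions are out of scope.
* The rasterizer is pure CPU numpy; a 256×256×100 build on a dense embryo
  takes seconds to a few minutes depending on mesh sizes, not the
  interactive rates a GPU implementation reaches.
* Membrane mode with a slab much thicker than the inter-cell spacing lets
  small-id cells claim their neighbors' pixels via the tie-break; keep ε
  of the order of the pixel size (the default) for dense packings.
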