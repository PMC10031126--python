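# sthcube

Space-Time Hypercube projection and rendering for 3D+t labeled biological
data — a headless library and CLI for turning a time series of segmented,
meshed objects (typically the cells of a developing embryo recorded by
light-sheet microscopy) into a single static 3D picture of their evolution.

## The idea

A 3D time-lapse recording is a 4D object: three spatial dimensions plus
time, (x, y, z, t). Scrolling through time on a 3D view forces the analyst
to remember what each frame looked like; events with a strong temporal
component — waves of near-simultaneous cell division, asynchronously
dividing cells, slow tissue deformation — are hard to see that way.

`sthcube` treats the recording as a *space-time hypercube* and projects it
through a user-chosen cutting plane:

    (x, y, z, t)  →  (u, v, t)

For each frame, the cross-section of the labeled geometry with the plane is
rasterized into a 2D image whose pixel values are object identifiers
(0 = background). The images — all sharing one orthographic frame, fitted
once to the union of the cross-section's bounds over the whole recording,
so there is no spatial distortion and no relative shift — are stacked into
a *space-time cube* (STC): a 3D voxel volume whose third axis is time. A
division wave becomes a visible branching front; a cell that skips a wave
becomes a tube that runs straight through it.

The STC is rendered with opaque direct volume rendering: one orthographic
ray per pixel, terminated at the first occupied voxel, shaded with the
Blinn-Phong model under a movable point light, using normals precomputed
from the volume occupancy with 3D Sobel-Feldman gradients. Colors come from
a per-(object id, time) lookup of any numerical or categorical annotation
(cell volume, remaining lifespan until division, fate labels, ...), so the
displayed property can be switched without touching the volume. Cutting
planes, a value filter, a time window, and lineage-aware highlight/hide
tracking (state changes propagate to all time instances and all descendant
cells) operate on one shared filter state.

Because the public embryo recordings the method targets are large external
downloads, the package ships a deterministic synthetic embryo generator —
sphere-like cells packed in an ellipsoid that jitter, divide in synchronous
waves (with optional asynchronous branches and a cavity-style deformation)
and carry a full ground-truth lineage and annotation table — so the whole
pipeline runs and is testable offline.

## Worked example

```python
import numpy as np
from sthcube import (SimulationParams, simulate, median_plane, build_stc,
                     compute_normals, build_lookup, RenderSettings, render_stc,
                     query_voxel, io)

params = SimulationParams(n_initial_cells=1, n_timesteps=14,
                          division_period=6, jitter_sigma=0.5, seed=7)
dataset, lineage, annotations = simulate(params)
plane = median_plane(dataset)                       # least-squares median plane
stc = build_stc(dataset, plane, resolution=(128, 128), mode="filled")

counts = [len(set(np.unique(stc.grid[:, :, k])) - {0}) for k in range(stc.n_times)]
print("cells per slice:", counts)

normals = compute_normals(stc)
lookup = build_lookup(annotations, "volume", colormap="viridis")
image = render_stc(stc, normals, lookup, RenderSettings(view_dir=(0.4, 0.3, -1)))
io.write_png(image, "stc_volume.png")

jj, ii = np.nonzero(stc.grid[:, :, 0])
record = query_voxel(stc, lookup, lineage, annotations, (int(ii[0]), int(jj[0]), 0))
print("root cell record:", {k: record[k] for k in ("id", "time", "value", "life_interval", "children")})
```

This prints

```
cells per slice: [1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 4, 4]
root cell record: {'id': 1, 'time': 0, 'value': 1591942.5228526266, 'life_interval': (0, 5), 'children': [2, 3]}
```

The per-slice count of distinct cell ids doubles right after each multiple
of the division period (frames 6 and 12) — the division-wave signature read
directly off the STC. The voxel query is the detail-on-demand operator: it
reports the cell under a voxel, the currently mapped annotation value (here
the cell volume in cubic world units), its life interval in frames and its
daughters. `stc_volume.png` is the shaded rendering of the cube.

The same pipeline is available from the shell:

```sh
stc simulate --out embryo/                      # dataset + lineage + annotations
stc build --data embryo/ --plane "0,0,0/0,0,1/0,1,0" --res 256x256 \
    --mode membrane --out stc.tiff
stc render --stc stc.tiff --annotations embryo/annotations.csv \
    --property volume --out view.png
stc cut --stc stc.tiff --cut "0,0,50/0,0,-1/1" --out early.tiff
stc query --stc stc.tiff --data embryo/ --voxel 64,64,10
```

## Layout

| module | contents |
| --- | --- |
| `sthcube.core` | `TemporalDataset`, `LineageTree`, `AnnotationTable`, `FilterState`, lineage propagation and validation |
| `sthcube.synthetic_embryo` | the seeded dividing-embryo generator |
| `sthcube.projection` | cutting plane, frame fitting, cross-section rasterization, STC stacking |
| `sthcube.volume_shading` | Sobel-Feldman normals, value lookups, opaque raycaster, cuts, voxel query |
| `sthcube.filters` | value / time / object-tracking filters over the shared state |
| `sthcube.io` | PLY/OBJ, multi-page TIFF, NRRD, CSV, YAML, PNG readers and writers |
| `sthcube.cli` | the `stc` command |

See `docs/methods.md` for the model, conventions and numerical choices.
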