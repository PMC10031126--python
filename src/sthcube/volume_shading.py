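"""Rendering of the Space-Time Cube: normals, colormaps, raycasting, cuts.

The STC is rendered with opaque direct volume rendering: one orthographic
ray per pixel, terminated at the first voxel that carries a nonzero id and
survives the active filters and cut.  Opacity (no semi-transparency) keeps
the colors faithful to the encoded information — each pixel shows exactly
one object instance.  Shading uses the Blinn-Phong model with a movable
point light; normals are precomputed once from the volume's occupancy with
3D Sobel-Feldman gradient kernels and reused for every render, since they
do not depend on the colormap, the light or the filters.

Coordinate convention: all user-facing positions and directions (light,
camera, cut planes, queried voxels) are in STC voxel coordinates
``(u, v, k)`` where voxel (i, j, k) has its center at (i, j, k); see
:class:`sthcube.projection.STCVolume`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from matplotlib import colormaps as _mpl_colormaps

from .core import (
    AnnotationTable,
    FilterState,
    LineageTree,
    NotFoundError,
    ValidationError,
)
from .projection import STCVolume

_SENTINEL_GRAY = (0.5, 0.5, 0.5)
_HIGHLIGHT_RED = np.array([1.0, 0.0, 0.0])
_CATEGORICAL_CMAP = "tab20"


# ---------------------------------------------------------------------------
# Normals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalField:
    """Per-voxel unit outward normals of the STC occupancy.

    ``vectors[j, i, k]`` is the (u, v, k)-component normal at voxel
    (i, j, k); the zero vector marks voxels with vanishing gradient
    (deep interior or empty regions).
    """

    vectors: np.ndarray  # (n_v, n_u, T, 3)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValidationError("normal field must have shape (n_v, n_u, T, 3)")


def compute_normals(stc: STCVolume, smooth_sigma: float = 1.0) -> NormalField:
    """Precompute outward surface normals from the STC's occupancy.

    The binary occupancy (id != 0) — optionally pre-smoothed with a Gaussian
    of ``smooth_sigma`` voxels, on by default — is differentiated with the
    3x3x3 Sobel-Feldman kernel along each axis.  Ids are nominal labels, so
    the occupancy, never the id values themselves, is what gets
    differentiated.  Normals point from object into background (against the
    occupancy gradient) and are unit length; voxels with vanishing gradient
    get the zero vector.  Borders are handled by edge replication.
    """
    occ = (stc.grid != 0).astype(np.float64)
    if smooth_sigma > 0:
        occ = ndimage.gaussian_filter(occ, smooth_sigma, mode="nearest")
    # component order (u, v, k) = array axes (1, 0, 2)
    g_u = ndimage.sobel(occ, axis=1, mode="nearest")
    g_v = ndimage.sobel(occ, axis=0, mode="nearest")
    g_k = ndimage.sobel(occ, axis=2, mode="nearest")
    g = np.stack([g_u, g_v, g_k], axis=-1)
    norm = np.linalg.norm(g, axis=-1)
    scale = np.where(norm > 1e-12, norm, 1.0)
    vectors = -g / scale[..., None]
    vectors[norm <= 1e-12] = 0.0
    return NormalField(vectors=vectors)


# ---------------------------------------------------------------------------
# Value lookup
# ---------------------------------------------------------------------------

class ValueLookup:
    """The per-(object id, time) value table with its colormap.

    Maps an (id, t) pair to a scalar or category and to an RGB color:
    numeric values are normalized over ``[vmin, vmax]`` and pushed through a
    matplotlib colormap; categories go through a deterministic categorical
    palette (CRC32 of the label, stable across runs and processes); missing
    entries get the sentinel gray.  Rebuilding a lookup for a different
    property touches neither the STC nor the normal field.
    """

    def __init__(
        self,
        property_name: str,
        table: dict[tuple[int, int], object],
        vmin: float | None,
        vmax: float | None,
        colormap: str,
        categorical: bool,
        sentinel: tuple[float, float, float] = _SENTINEL_GRAY,
    ):
        self.property_name = property_name
        self._table = table
        self.vmin = vmin
        self.vmax = vmax
        self.colormap = colormap
        self.categorical = categorical
        self.sentinel = np.asarray(sentinel, dtype=float)
        self._cmap = _mpl_colormaps[colormap]

    def value(self, oid: int, t: int):
        """Raw annotated value for (id, t), or None if missing."""
        return self._table.get((int(oid), int(t)))

    def color(self, oid: int, t: int) -> np.ndarray:
        v = self.value(oid, t)
        if v is None:
            return self.sentinel.copy()
        if self.categorical:
            idx = zlib.crc32(str(v).encode("utf8")) % self._cmap.N
            return np.asarray(self._cmap(idx)[:3], dtype=float)
        if self.vmax == self.vmin:
            x = 0.0
        else:
            x = (float(v) - self.vmin) / (self.vmax - self.vmin)
        return np.asarray(self._cmap(float(np.clip(x, 0.0, 1.0)))[:3], dtype=float)


def build_lookup(
    annotations: AnnotationTable,
    property_name: str,
    colormap: str = "viridis",
    value_range: tuple[float, float] | None = None,
) -> ValueLookup:
    """Build the (id, time) -> color lookup for one annotated property.

    Numeric properties are normalized over ``value_range`` (or the table's
    min/max when not given); non-numeric properties are treated as
    categories with a stable hashed palette.

    Raises
    ------
    NotFoundError
        If the property does not exist in the annotation table.
    """
    table = annotations.table(property_name)  # raises NotFoundError
    values = list(table.values())
    numeric = all(isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool) for v in values)
    if numeric and values:
        if value_range is not None:
            vmin, vmax = float(value_range[0]), float(value_range[1])
        else:
            vmin = float(min(values))
            vmax = float(max(values))
        return ValueLookup(property_name, table, vmin, vmax, colormap, categorical=False)
    return ValueLookup(property_name, table, None, None, _CATEGORICAL_CMAP, categorical=True)


# ---------------------------------------------------------------------------
# Cuts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutSpec:
    """A clipping plane on the STC, in voxel coordinates (u, v, k).

    Voxels with ``sign((center - point) . normal) * keep_side < 0`` are
    discarded; voxels exactly on the plane are kept.  A normal along the
    time axis gives a time cut, an in-plane normal a linear space cut, and
    anything in between an oblique cut (useful to follow slowly drifting
    objects through time).
    """

    point: np.ndarray
    normal: np.ndarray
    keep_side: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        if np.linalg.norm(self.normal) < 1e-12:
            raise ValidationError("cut normal must be nonzero")
        if self.keep_side not in (-1, 1):
            raise ValidationError("keep_side must be +1 or -1")

    def keep_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean (n_v, n_u, T) mask of voxels on the kept side."""
        n_v, n_u, T = shape
        i = np.arange(n_u, dtype=float)
        j = np.arange(n_v, dtype=float)
        k = np.arange(T, dtype=float)
        s = (
            (i[None, :, None] - self.point[0]) * self.normal[0]
            + (j[:, None, None] - self.point[1]) * self.normal[1]
            + (k[None, None, :] - self.point[2]) * self.normal[2]
        )
        return s * self.keep_side >= 0


def cut_stc(stc: STCVolume, cut: CutSpec) -> STCVolume:
    """Apply a clipping plane to the STC, zeroing the discarded side.

    The stored volume is immutable; a new :class:`STCVolume` is returned.
    A time cut with the plane at slice K (normal along -k, keep_side +1)
    leaves slices 0..K intact and zeroes the rest.
    """
    keep = cut.keep_mask(stc.shape)
    grid = np.where(keep, stc.grid, np.uint32(0)).astype(stc.grid.dtype)
    return stc.with_grid(grid)


# ---------------------------------------------------------------------------
# Raycasting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderSettings:
    """Camera, light and material settings for the STC renderer.

    All positions/directions are in STC voxel coordinates (u, v, k).  The
    camera is orthographic by default (no perspective distortion of the
    time axis); ``image_shape`` is (height, width) in pixels, fitted to the
    volume when None.  ``pixel_scale`` is voxels per pixel.  The Blinn-Phong
    coefficients default to an unremarkable matte-plus-sheen material; the
    point light has no distance attenuation and can be moved freely without
    changing which voxel each ray hits.
    """

    view_dir: tuple[float, float, float] = (0.0, 0.0, -1.0)
    up: tuple[float, float, float] = (0.0, 1.0, 0.0)
    image_shape: tuple[int, int] | None = None
    pixel_scale: float = 1.0
    light_pos: tuple[float, float, float] = (-50.0, -50.0, 200.0)
    ka: float = 0.2
    kd: float = 0.7
    ks: float = 0.3
    shininess: float = 16.0
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    step: float = 0.5
    unsafe_coefficients: bool = False

    def __post_init__(self) -> None:
        if np.linalg.norm(self.view_dir) < 1e-12:
            raise ValidationError("view direction must be nonzero")
        if min(self.ka, self.kd, self.ks) < 0:
            raise ValidationError("Blinn-Phong coefficients must be >= 0")
        if not self.unsafe_coefficients and self.ka + self.kd > 1.2:
            raise ValidationError("ka + kd > 1.2; pass unsafe_coefficients=True to override")
        if self.step <= 0:
            raise ValidationError("step must be positive")


def _camera_rays(stc: STCVolume, settings: RenderSettings):
    """Orthographic ray origins (one per pixel) and the shared direction.

    Returns (origins (H, W, 3), direction (3,)) in (u, v, k) voxel coords.
    """
    d = np.asarray(settings.view_dir, dtype=float)
    d = d / np.linalg.norm(d)
    up = np.asarray(settings.up, dtype=float)
    up_orth = up - (up @ d) * d
    if np.linalg.norm(up_orth) < 1e-9:
        up_orth = np.array([0.0, 1.0, 0.0])
        up_orth = up_orth - (up_orth @ d) * d
        if np.linalg.norm(up_orth) < 1e-9:
            up_orth = np.array([1.0, 0.0, 0.0])
            up_orth = up_orth - (up_orth @ d) * d
    v_img = up_orth / np.linalg.norm(up_orth)
    u_img = np.cross(v_img, d)

    n_v, n_u, T = stc.shape
    corners = np.array(
        [[i, j, k] for i in (-0.5, n_u - 0.5) for j in (-0.5, n_v - 0.5) for k in (-0.5, T - 0.5)],
        dtype=float,
    )
    center = np.array([(n_u - 1) / 2, (n_v - 1) / 2, (T - 1) / 2])
    rel = corners - center
    eu = rel @ u_img
    ev = rel @ v_img
    if settings.image_shape is None:
        W = int(np.ceil((eu.max() - eu.min()) / settings.pixel_scale))
        H = int(np.ceil((ev.max() - ev.min()) / settings.pixel_scale))
        W, H = max(W, 1), max(H, 1)
    else:
        H, W = settings.image_shape
    diag = float(np.linalg.norm([n_u, n_v, T]))
    plane_center = center - d * diag
    xs = (np.arange(W) - (W - 1) / 2) * settings.pixel_scale
    ys = (np.arange(H) - (H - 1) / 2) * settings.pixel_scale
    origins = (
        plane_center[None, None, :]
        + xs[None, :, None] * u_img[None, None, :]
        + ys[:, None, None] * v_img[None, None, :]
    )
    return origins, d


def raycast_first_hit(
    stc: STCVolume,
    settings: RenderSettings,
    mask: np.ndarray | None = None,
    cut: CutSpec | None = None,
) -> np.ndarray:
    """First-hit voxel per pixel for opaque raycasting.

    Marches each orthographic ray through the volume in steps of
    ``settings.step`` voxels (0.5 by default) and records the first voxel
    that carries a nonzero id, survives ``mask`` (a boolean keep-volume, as
    produced by :func:`sthcube.filters.apply_filters`) and lies on the kept
    side of ``cut``.  Returns an (H, W, 3) int array of array indices
    (j, i, k); (-1, -1, -1) where the ray hits nothing.  The result is what
    makes the rendering opaque: everything behind the first hit is
    invisible by construction.
    """
    keep = stc.grid != 0
    if mask is not None:
        if mask.shape != stc.grid.shape:
            raise ValidationError("mask shape does not match the STC")
        keep = keep & mask
    if cut is not None:
        keep = keep & cut.keep_mask(stc.shape)

    origins, d = _camera_rays(stc, settings)
    H, W = origins.shape[:2]
    n_v, n_u, T = stc.shape

    # slab clip against the voxel-extent box [-0.5, N-0.5] per axis
    lo = np.array([-0.5, -0.5, -0.5])
    hi = np.array([n_u - 0.5, n_v - 0.5, T - 0.5])
    o = origins.reshape(-1, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - o) / d
        t2 = (hi - o) / d
    t1 = np.where(np.isfinite(t1), t1, np.where((o >= lo) & (o <= hi), -np.inf, np.nan))
    t2 = np.where(np.isfinite(t2), t2, np.where((o >= lo) & (o <= hi), np.inf, np.nan))
    near = np.nanmax(np.minimum(t1, t2), axis=1)
    far = np.nanmin(np.maximum(t1, t2), axis=1)
    valid = far >= near

    hits = np.full((H * W, 3), -1, dtype=np.int64)
    active = np.nonzero(valid)[0]
    s = np.maximum(near[active], 0.0)
    s_end = far[active]
    step = settings.step
    while len(active):
        pos = o[active] + s[:, None] * d
        idx = np.rint(pos).astype(np.int64)  # voxel centers at integers
        inside = (
            (idx[:, 0] >= 0) & (idx[:, 0] < n_u)
            & (idx[:, 1] >= 0) & (idx[:, 1] < n_v)
            & (idx[:, 2] >= 0) & (idx[:, 2] < T)
        )
        hit = np.zeros(len(active), dtype=bool)
        ii = idx[inside]
        hit[inside] = keep[ii[:, 1], ii[:, 0], ii[:, 2]]
        if hit.any():
            h = np.nonzero(hit)[0]
            hits[active[h], 0] = idx[h, 1]
            hits[active[h], 1] = idx[h, 0]
            hits[active[h], 2] = idx[h, 2]
        cont = ~hit & (s + step <= s_end)
        active = active[cont]
        s = s[cont] + step
        s_end = s_end[cont]
    return hits.reshape(H, W, 3)


def render_stc(
    stc: STCVolume,
    normals: NormalField,
    lookup: ValueLookup | None,
    settings: RenderSettings,
    filters: FilterState | None = None,
    cut: CutSpec | None = None,
    return_hits: bool = False,
):
    """Render the STC with opaque first-hit raycasting and Blinn-Phong.

    Each pixel's base color C is the lookup color of the hit voxel's
    (id, time) — overridden to solid red for highlighted ids — and the
    shaded color is

        ka*C + kd*max(N.L, 0)*C + ks*max(N.H, 0)^shininess

    with N the precomputed voxel normal, L the direction to the point
    light, H the half-vector between L and the view direction, everything
    clamped to [0, 1].  Voxels with an undefined (zero) normal receive the
    ambient term only.  Rays that hit nothing show the background color.

    Returns a float RGB image of shape (H, W, 3); with ``return_hits=True``
    also the (H, W, 3) first-hit index map.
    """
    if normals.vectors.shape[:3] != stc.grid.shape:
        raise ValidationError("normal field does not match the STC dimensions")
    mask = None
    highlighted: set[int] = set()
    if filters is not None:
        from .filters import apply_filters

        mask = apply_filters(stc, lookup, filters)
        highlighted = filters.highlighted_ids()

    hits = raycast_first_hit(stc, settings, mask=mask, cut=cut)
    H, W = hits.shape[:2]
    img = np.empty((H, W, 3), dtype=float)
    img[:] = np.asarray(settings.background, dtype=float)

    hit_px = hits[:, :, 0] >= 0
    if not hit_px.any():
        return (img, hits) if return_hits else img

    jj, ii, kk = hits[hit_px, 0], hits[hit_px, 1], hits[hit_px, 2]
    ids = stc.grid[jj, ii, kk]
    times = np.asarray(stc.times) if stc.times else np.arange(stc.n_times)
    ts = times[kk]

    # base colors
    C = np.empty((len(ids), 3), dtype=float)
    if lookup is None:
        C[:] = 0.8
    else:
        cache: dict[tuple[int, int], np.ndarray] = {}
        for n, (oid, t) in enumerate(zip(ids, ts)):
            key = (int(oid), int(t))
            if key not in cache:
                cache[key] = lookup.color(*key)
            C[n] = cache[key]
    if highlighted:
        C[np.isin(ids, list(highlighted))] = _HIGHLIGHT_RED

    # shading
    d = np.asarray(settings.view_dir, dtype=float)
    d = d / np.linalg.norm(d)
    V = -d
    N = normals.vectors[jj, ii, kk]
    pos = np.stack([ii, jj, kk], axis=1).astype(float)  # (u, v, k)
    L = np.asarray(settings.light_pos, dtype=float)[None, :] - pos
    L_len = np.linalg.norm(L, axis=1, keepdims=True)
    L = L / np.where(L_len > 1e-12, L_len, 1.0)
    Hv = L + V[None, :]
    H_len = np.linalg.norm(Hv, axis=1, keepdims=True)
    Hv = Hv / np.where(H_len > 1e-12, H_len, 1.0)

    n_def = np.linalg.norm(N, axis=1) > 0.5
    ndl = np.clip(np.einsum("pk,pk->p", N, L), 0.0, None)
    ndh = np.clip(np.einsum("pk,pk->p", N, Hv), 0.0, None)
    diffuse = np.where(n_def, ndl, 0.0)
    specular = np.where(n_def, ndh**settings.shininess, 0.0)

    color = settings.ka * C + settings.kd * diffuse[:, None] * C + settings.ks * specular[:, None]
    img[hit_px] = np.clip(color, 0.0, 1.0)
    return (img, hits) if return_hits else img


# ---------------------------------------------------------------------------
# Detail-on-demand query
# ---------------------------------------------------------------------------

def query_voxel(
    stc: STCVolume,
    lookup: ValueLookup | None,
    lineage: LineageTree | None,
    annotations: AnnotationTable | None,
    voxel: tuple[int, int, int],
) -> dict:
    """Summarize the object instance under one STC voxel (i, j, k).

    Returns a record with the object id, the time index of the slice, the
    currently mapped property value, the id's life interval and its parent
    and children ids; a background voxel yields ``{"background": True,
    "time": t}``.  Voxels outside the volume raise a validation error.
    """
    i, j, k = (int(x) for x in voxel)
    n_v, n_u, T = stc.shape
    if not (0 <= i < n_u and 0 <= j < n_v and 0 <= k < T):
        raise ValidationError(f"voxel {(i, j, k)} outside volume of shape (u={n_u}, v={n_v}, t={T})")
    t = stc.times[k] if stc.times else k
    oid = int(stc.grid[j, i, k])
    if oid == 0:
        return {"background": True, "time": t, "voxel": (i, j, k)}
    rec: dict = {"background": False, "id": oid, "time": t, "voxel": (i, j, k)}
    if lookup is not None:
        rec["property"] = lookup.property_name
        rec["value"] = lookup.value(oid, t)
    elif annotations is not None:
        rec["annotations"] = {p: annotations.get(p, oid, t) for p in annotations.properties}
    if lineage is not None and oid in lineage:
        rec["life_interval"] = lineage.interval(oid)
        rec["parent"] = lineage.parent(oid)
        rec["children"] = lineage.children(oid)
    return rec
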