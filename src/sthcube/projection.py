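"""Projection of the 4D space-time hypercube into a 3D Space-Time Cube.

The user supplies a cutting plane; an orthographic frame perpendicular to
that plane is fitted once, to the union over *all* time steps of the
cross-section's bounding rectangle (so the per-time slices stack into a
spatially aligned volume).  Each time step is rasterized into a 2D label
image — pixel values are object ids, 0 is background — and the images are
stacked along the third axis, which therefore encodes time:

    (x, y, z, t)  →  (u, v, t)

with (u, v) the in-plane coordinates.  Because the projection is a rigid
in-plane parameterization, in-plane distances in the image equal 3D
distances in the world: there is no spatial distortion.

Two rasterization modes exist.  ``membrane`` labels a pixel when an
object's *surface* passes within ``max(eps, half pixel diagonal)`` of the
pixel center (eps is the half-thickness of the slab captured around the
plane); this matches datasets of hollow surface meshes, where a
cross-section shows cell membranes.  ``filled`` labels every pixel whose
center lies inside the closed mesh (even-odd parity against the mesh's
plane section), producing region-like images.  When several objects claim
one pixel the smallest id wins — a deterministic, order-independent
tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .core import (
    LabeledObject,
    LabelVolumeFrame,
    NotFoundError,
    TemporalDataset,
    ValidationError,
)

MODES = ("membrane", "filled")

_TRI_CHUNK = 128  # triangles per distance-computation chunk (memory bound)


# ---------------------------------------------------------------------------
# Plane and frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneSpec:
    """A cutting plane: a point on it, its unit normal, and an in-plane
    "up" direction.  The in-plane basis is ``u = up × normal`` and
    ``v = up`` (after orthogonalization), so (u, v, normal) is right-handed.
    """

    point: np.ndarray
    normal: np.ndarray
    up: np.ndarray

    @property
    def u_axis(self) -> np.ndarray:
        return np.cross(self.up, self.normal)

    @property
    def v_axis(self) -> np.ndarray:
        return self.up

    def to_uvw(self, points: np.ndarray) -> np.ndarray:
        """World points -> (u, v, w) plane coordinates; w is the signed
        distance to the plane."""
        rel = np.asarray(points, dtype=float) - self.point
        return np.stack(
            [rel @ self.u_axis, rel @ self.v_axis, rel @ self.normal], axis=-1
        )


def define_plane(point, normal, up) -> PlaneSpec:
    """Construct a validated :class:`PlaneSpec`.

    The normal is normalized; ``up`` is replaced by its component orthogonal
    to the normal (Gram-Schmidt) and normalized.
    """
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    up = np.asarray(up, dtype=float)
    if point.shape != (3,) or normal.shape != (3,) or up.shape != (3,):
        raise ValidationError("point, normal and up must be 3-vectors")
    n_len = np.linalg.norm(normal)
    if n_len < 1e-12:
        raise ValidationError("plane normal must be nonzero")
    n = normal / n_len
    up_orth = up - (up @ n) * n
    u_len = np.linalg.norm(up_orth)
    if u_len < 1e-12:
        raise ValidationError("up vector must not be parallel to the normal")
    return PlaneSpec(point=point, normal=n, up=up_orth / u_len)


def median_plane(dataset: TemporalDataset, up=None) -> PlaneSpec:
    """Fit a cutting plane close to the dataset's median plane.

    Total least squares over the centroids of every (object, time)
    instance: the plane passes through the global centroid with its normal
    along the direction of least centroid variance, which is the plane that
    keeps the cell population closest to the cross-section over the whole
    recording — the usual starting plane when exploring an embryo.
    ``up`` defaults to the world axis least aligned with the normal.
    """
    pts = []
    for t in dataset.times:
        for obj in dataset.objects(t):
            if obj.is_mesh:
                pts.append(np.asarray(obj.mesh.vertices).mean(axis=0))
            else:
                occ = np.argwhere(obj.voxels.labels == obj.id)
                if len(occ):
                    pts.append(obj.voxels.origin + (occ.mean(axis=0) + 0.5) * obj.voxels.spacing)
    if not pts:
        raise ValidationError("dataset contains no geometry to fit a plane to")
    pts = np.asarray(pts)
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T) if len(pts) > 1 else np.eye(3)
    w, v = np.linalg.eigh(np.atleast_2d(cov))
    normal = v[:, 0]  # smallest-variance direction
    if up is None:
        up = np.eye(3)[int(np.argmin(np.abs(normal)))]
    return define_plane(center, normal, up)


@dataclass(frozen=True)
class CameraFrame:
    """The orthographic frame shared by every time step.

    ``origin`` is the world position of the frame corner; pixel (i, j) —
    i the u-column, j the v-row — has its center at

        origin + (i + 0.5) * pixel_size * u_axis + (j + 0.5) * pixel_size * v_axis

    Pixels are square; ``eps`` is the slab half-thickness captured around
    the plane.
    """

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    width: float
    height: float
    resolution: tuple[int, int]  # (n_u, n_v)
    eps: float

    @property
    def pixel_size(self) -> float:
        return self.width / self.resolution[0]

    def pixel_centers(self) -> np.ndarray:
        """World coordinates of all pixel centers, shape (n_v, n_u, 3)."""
        n_u, n_v = self.resolution
        px = self.pixel_size
        i = (np.arange(n_u) + 0.5) * px
        j = (np.arange(n_v) + 0.5) * px
        return (
            self.origin[None, None, :]
            + i[None, :, None] * self.u_axis[None, None, :]
            + j[:, None, None] * self.v_axis[None, None, :]
        )

    def uv_of_pixels(self) -> tuple[np.ndarray, np.ndarray]:
        """In-frame (u, v) coordinates of pixel centers (1D arrays)."""
        n_u, n_v = self.resolution
        px = self.pixel_size
        return (np.arange(n_u) + 0.5) * px, (np.arange(n_v) + 0.5) * px

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "u_axis": self.u_axis.tolist(),
            "v_axis": self.v_axis.tolist(),
            "width": self.width,
            "height": self.height,
            "resolution": list(self.resolution),
            "eps": self.eps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraFrame":
        return cls(
            origin=np.asarray(d["origin"], dtype=float),
            u_axis=np.asarray(d["u_axis"], dtype=float),
            v_axis=np.asarray(d["v_axis"], dtype=float),
            width=float(d["width"]),
            height=float(d["height"]),
            resolution=(int(d["resolution"][0]), int(d["resolution"][1])),
            eps=float(d["eps"]),
        )


@dataclass(frozen=True)
class LabelImage:
    """One rasterized cross-section: a (n_v, n_u) grid of object ids."""

    data: np.ndarray
    t: int
    frame: CameraFrame


@dataclass(frozen=True)
class STCVolume:
    """The Space-Time Cube: object ids on a (n_v, n_u, T) grid.

    ``grid[j, i, k]`` is the id at u-column i, v-row j, time slice k;
    slice k is voxel-for-voxel the label image of time ``times[k]``.
    In STC voxel coordinates — used by cuts, the renderer and queries —
    voxel (i, j, k) has its center at (i, j, k) in (u, v, time) order; the
    in-plane voxel size in world units is ``frame.pixel_size``, the step
    along the third axis is one frame.
    """

    grid: np.ndarray
    plane: PlaneSpec
    frame: CameraFrame
    mode: str
    times: tuple[int, ...] = field(default=())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_times(self) -> int:
        return self.grid.shape[2]

    def slice(self, k: int) -> np.ndarray:
        return self.grid[:, :, k]

    def with_grid(self, grid: np.ndarray) -> "STCVolume":
        return STCVolume(grid=grid, plane=self.plane, frame=self.frame, mode=self.mode, times=self.times)


# ---------------------------------------------------------------------------
# Frame fitting
# ---------------------------------------------------------------------------

def _object_uv_bounds(obj: LabeledObject, plane: PlaneSpec, eps: float) -> np.ndarray | None:
    """(u, v) bounding box of the part of one object inside the plane slab,
    or None if it misses the slab entirely.  Shape (2, 2): [[umin, vmin],
    [umax, vmax]]."""
    pts = []
    if obj.is_mesh:
        segs = trimesh.intersections.mesh_plane(obj.mesh, plane.normal, plane.point)
        if len(segs):
            pts.append(segs.reshape(-1, 3))
        if eps > 0:
            uvw = plane.to_uvw(obj.mesh.vertices)
            near = np.abs(uvw[:, 2]) <= eps
            if near.any():
                pts.append(np.asarray(obj.mesh.vertices)[near])
    else:
        vol = obj.voxels
        occ = np.argwhere(vol.labels == obj.id)
        if len(occ):
            centers = vol.origin + (occ + 0.5) * vol.spacing
            half_diag = 0.5 * float(np.linalg.norm(vol.spacing))
            uvw = plane.to_uvw(centers)
            near = np.abs(uvw[:, 2]) <= max(eps, half_diag)
            if near.any():
                pts.append(centers[near])
    if not pts:
        return None
    uvw = plane.to_uvw(np.vstack(pts))
    return np.stack([uvw[:, :2].min(axis=0), uvw[:, :2].max(axis=0)])


def fit_frame(
    dataset: TemporalDataset,
    plane: PlaneSpec,
    resolution: tuple[int, int] = (256, 256),
    margin_fraction: float = 0.02,
    eps: float | None = None,
) -> CameraFrame:
    """Fit the shared orthographic frame to the whole time series.

    The frame's (u, v) rectangle is the union over all time steps of the
    cross-section's bounding rectangle, expanded by ``margin_fraction`` on
    each side, then padded (centered) so that pixels come out square.  The
    same frame is used at every time step so the slices stack without any
    relative shift.

    ``eps=None`` resolves to one pixel's world size (computed from a first
    bounding pass with a zero-thickness slab).

    Raises
    ------
    ValidationError
        If no geometry intersects the plane slab at any time step.
    """
    n_u, n_v = int(resolution[0]), int(resolution[1])
    if n_u < 1 or n_v < 1:
        raise ValidationError("resolution must be positive")

    def union_bounds(eps_used: float) -> np.ndarray | None:
        lo = np.full(2, np.inf)
        hi = np.full(2, -np.inf)
        found = False
        for t in dataset.times:
            for obj in dataset.objects(t):
                b = _object_uv_bounds(obj, plane, eps_used)
                if b is not None:
                    found = True
                    lo = np.minimum(lo, b[0])
                    hi = np.maximum(hi, b[1])
        return np.stack([lo, hi]) if found else None

    bounds = union_bounds(0.0 if eps is None else eps)
    if bounds is None and eps is None:
        bounds = union_bounds(0.0)
    if bounds is None:
        raise ValidationError("no geometry intersects the cutting plane slab at any time step")

    if eps is None:
        # provisional pixel size from the tight bound, then refit with the slab
        w0 = max(bounds[1][0] - bounds[0][0], 1e-12) * (1 + 2 * margin_fraction)
        h0 = max(bounds[1][1] - bounds[0][1], 1e-12) * (1 + 2 * margin_fraction)
        eps_used = max(w0 / n_u, h0 / n_v)
        refit = union_bounds(eps_used)
        if refit is not None:
            bounds = refit
    else:
        eps_used = float(eps)

    size = np.maximum(bounds[1] - bounds[0], 1e-12)
    lo = bounds[0] - margin_fraction * size
    hi = bounds[1] + margin_fraction * size
    w, h = hi - lo
    center = 0.5 * (lo + hi)
    px = max(w / n_u, h / n_v)
    width, height = px * n_u, px * n_v
    origin_uv = center - 0.5 * np.array([width, height])
    origin = plane.point + origin_uv[0] * plane.u_axis + origin_uv[1] * plane.v_axis
    return CameraFrame(
        origin=origin,
        u_axis=plane.u_axis,
        v_axis=plane.v_axis,
        width=float(width),
        height=float(height),
        resolution=(n_u, n_v),
        eps=eps_used,
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _points_to_triangles_min_dist(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each point to a set of triangles.

    Vectorized point/triangle distance (barycentric clamping, Ericson's
    region walk).  ``points`` is (P, 3), ``tris`` is (T, 3, 3); returns (P,).
    """
    P = len(points)
    best = np.full(P, np.inf)
    for s in range(0, len(tris), _TRI_CHUNK):
        tri = tris[s : s + _TRI_CHUNK]
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        ab = b - a
        ac = c - a
        p = points[:, None, :]  # (P, 1, 3)
        ap = p - a[None, :, :]
        d1 = np.einsum("ptk,tk->pt", ap, ab)
        d2 = np.einsum("ptk,tk->pt", ap, ac)
        bp = p - b[None, :, :]
        d3 = np.einsum("ptk,tk->pt", bp, ab)
        d4 = np.einsum("ptk,tk->pt", bp, ac)
        cp = p - c[None, :, :]
        d5 = np.einsum("ptk,tk->pt", cp, ab)
        d6 = np.einsum("ptk,tk->pt", cp, ac)

        vc = d1 * d4 - d3 * d2
        vb = d5 * d2 - d1 * d6
        va = d3 * d6 - d5 * d4

        # default: interior projection via barycentric coordinates
        denom = va + vb + vc
        denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
        v = vb / denom
        w = vc / denom
        # closest point, then overridden for edge/vertex regions
        closest = a[None, :, :] + v[..., None] * ab[None, :, :] + w[..., None] * ac[None, :, :]

        # vertex regions
        reg_a = (d1 <= 0) & (d2 <= 0)
        reg_b = (d3 >= 0) & (d4 <= d3)
        reg_c = (d6 >= 0) & (d5 <= d6)
        # edge regions
        t_ab = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
        reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        t_ac = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
        reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        t_bc = np.divide(d4 - d3, (d4 - d3) + (d5 - d6), out=np.zeros_like(d4), where=((d4 - d3) + (d5 - d6)) != 0)
        reg_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

        on_ab = a[None, :, :] + np.clip(t_ab, 0, 1)[..., None] * ab[None, :, :]
        on_ac = a[None, :, :] + np.clip(t_ac, 0, 1)[..., None] * ac[None, :, :]
        on_bc = b[None, :, :] + np.clip(t_bc, 0, 1)[..., None] * (c - b)[None, :, :]

        closest = np.where(reg_bc[..., None], on_bc, closest)
        closest = np.where(reg_ac[..., None], on_ac, closest)
        closest = np.where(reg_ab[..., None], on_ab, closest)
        closest = np.where(reg_c[..., None], c[None, :, :], closest)
        closest = np.where(reg_b[..., None], b[None, :, :], closest)
        closest = np.where(reg_a[..., None], a[None, :, :], closest)

        d = np.linalg.norm(p - closest, axis=2).min(axis=1)
        best = np.minimum(best, d)
    return best


def _parity_inside(px_u: np.ndarray, px_v: np.ndarray, segs_uv: np.ndarray) -> np.ndarray:
    """Even-odd test of pixel centers against an unordered set of 2D
    segments (the mesh's plane section).  Counts crossings of the +u ray
    from each pixel using the half-open rule, so shared segment endpoints
    are never double-counted.  Shapes: px_u (P,), px_v (P,),
    segs_uv (S, 2, 2); returns boolean (P,)."""
    u1, v1 = segs_uv[:, 0, 0], segs_uv[:, 0, 1]
    u2, v2 = segs_uv[:, 1, 0], segs_uv[:, 1, 1]
    pv = px_v[:, None]
    straddle = (v1[None, :] > pv) != (v2[None, :] > pv)
    dv = v2 - v1
    dv = np.where(dv == 0, 1.0, dv)
    u_int = u1[None, :] + (pv - v1[None, :]) * (u2 - u1)[None, :] / dv[None, :]
    crossings = (straddle & (u_int > px_u[:, None])).sum(axis=1)
    return (crossings % 2) == 1


def rasterize_cross_section(
    dataset: TemporalDataset,
    t: int,
    plane: PlaneSpec,
    frame: CameraFrame,
    mode: str = "membrane",
) -> LabelImage:
    """Rasterize the cross-section of one time step into a label image.

    Pixel (i, j) is labeled with an object's id when — ``membrane`` mode —
    the object's surface passes within ``max(frame.eps, half pixel
    diagonal)`` of the pixel center, or — ``filled`` mode — the pixel
    center lies inside the object's closed mesh.  Contested pixels go to
    the smallest id; untouched pixels stay 0.  Non-watertight meshes are
    skipped in filled mode with a warning.  Label-volume objects are
    sampled at pixel centers by nearest neighbor (labels are nominal and
    must never be interpolated), identically in both modes.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    n_u, n_v = frame.resolution
    image = np.zeros((n_v, n_u), dtype=np.uint32)
    centers = frame.pixel_centers()  # (n_v, n_u, 3)
    us, vs = frame.uv_of_pixels()
    px = frame.pixel_size
    half_diag = 0.5 * px * np.sqrt(2.0)
    delta = max(frame.eps, half_diag)

    # frame-local uv of every pixel (frame origin at uv (0,0))
    frame_origin_uvw = plane.to_uvw(frame.origin[None, :])[0]

    sampled_volumes: dict[int, np.ndarray] = {}
    flat_centers = centers.reshape(-1, 3)

    for obj in sorted(dataset.objects(t), key=lambda o: o.id):
        if not obj.is_mesh:
            key = id(obj.voxels)
            if key not in sampled_volumes:
                sampled_volumes[key] = obj.voxels.sample_nearest(flat_centers).reshape(n_v, n_u)
            sel = (sampled_volumes[key] == obj.id) & (image == 0)
            image[sel] = obj.id
            continue

        mesh = obj.mesh
        uvw = plane.to_uvw(np.asarray(mesh.vertices)) - frame_origin_uvw

        if mode == "filled":
            if not mesh.is_watertight:
                warnings.warn(
                    f"object {obj.id} at t={t} is not watertight; skipped in filled mode",
                    stacklevel=2,
                )
                continue
            segs = trimesh.intersections.mesh_plane(mesh, plane.normal, plane.point)
            if not len(segs):
                continue
            segs_uvw = plane.to_uvw(segs.reshape(-1, 3)).reshape(-1, 2, 3)
            segs_uv = segs_uvw[:, :, :2] - frame_origin_uvw[:2]
            lo = segs_uv.reshape(-1, 2).min(axis=0)
            hi = segs_uv.reshape(-1, 2).max(axis=0)
            i_sel = np.nonzero((us >= lo[0]) & (us <= hi[0]))[0]
            j_sel = np.nonzero((vs >= lo[1]) & (vs <= hi[1]))[0]
            if not len(i_sel) or not len(j_sel):
                continue
            jj, ii = np.meshgrid(j_sel, i_sel, indexing="ij")
            jj, ii = jj.ravel(), ii.ravel()
            free = image[jj, ii] == 0
            jj, ii = jj[free], ii[free]
            if not len(jj):
                continue
            inside = _parity_inside(us[ii], vs[jj], segs_uv)
            image[jj[inside], ii[inside]] = obj.id
        else:  # membrane
            w = uvw[:, 2]
            tri_w = w[np.asarray(mesh.faces)]
            near_tri = (tri_w.min(axis=1) <= delta) & (tri_w.max(axis=1) >= -delta)
            if not near_tri.any():
                continue
            tris = np.asarray(mesh.triangles)[near_tri]
            tri_uv = uvw[:, :2][np.asarray(mesh.faces)[near_tri]]
            lo = tri_uv.reshape(-1, 2).min(axis=0) - delta
            hi = tri_uv.reshape(-1, 2).max(axis=0) + delta
            i_sel = np.nonzero((us >= lo[0]) & (us <= hi[0]))[0]
            j_sel = np.nonzero((vs >= lo[1]) & (vs <= hi[1]))[0]
            if not len(i_sel) or not len(j_sel):
                continue
            jj, ii = np.meshgrid(j_sel, i_sel, indexing="ij")
            jj, ii = jj.ravel(), ii.ravel()
            free = image[jj, ii] == 0
            jj, ii = jj[free], ii[free]
            if not len(jj):
                continue
            pts = centers[jj, ii]
            dist = _points_to_triangles_min_dist(pts, tris)
            hit = dist <= delta
            image[jj[hit], ii[hit]] = obj.id

    return LabelImage(data=image, t=t, frame=frame)


def build_stc(
    dataset: TemporalDataset,
    plane: PlaneSpec,
    resolution: tuple[int, int] = (256, 256),
    mode: str = "membrane",
    margin_fraction: float = 0.02,
    eps: float | None = None,
) -> STCVolume:
    """Project a whole time series through the plane into a Space-Time Cube.

    Fits the shared frame once, rasterizes every time step, and stacks the
    label images along the third axis; slice k of the result is exactly the
    label image of time ``times[k]``.
    """
    frame = fit_frame(dataset, plane, resolution=resolution, margin_fraction=margin_fraction, eps=eps)
    n_u, n_v = frame.resolution
    T = dataset.n_times
    grid = np.zeros((n_v, n_u, T), dtype=np.uint32)
    for k, t in enumerate(dataset.times):
        grid[:, :, k] = rasterize_cross_section(dataset, t, plane, frame, mode=mode).data
    return STCVolume(grid=grid, plane=plane, frame=frame, mode=mode, times=tuple(dataset.times))
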