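"""Volume shading: normals, lookups, opaque raycasting, cuts, queries."""

import numpy as np
import pytest

from sthcube import (
    CutSpec,
    FilterState,
    LineageTree,
    NormalField,
    RenderSettings,
    ValidationError,
    build_lookup,
    build_stc,
    compute_normals,
    cut_stc,
    query_voxel,
    raycast_first_hit,
    render_stc,
)
from sthcube.core import AnnotationTable

from conftest import MEDIAN_PLANE, make_stc, sphere_dataset


def brute_force_first_hits(stc, settings, step=0.25):
    """Independent exhaustive ray marcher (floor-based voxel lookup)."""
    from sthcube.volume_shading import _camera_rays

    origins, d = _camera_rays(stc, settings)
    n_v, n_u, T = stc.shape
    H, W = origins.shape[:2]
    hits = np.full((H, W, 3), -1, dtype=int)
    lo = np.array([-0.5, -0.5, -0.5])
    hi = np.array([n_u - 0.5, n_v - 0.5, T - 0.5])
    for y in range(H):
        for x in range(W):
            o = origins[y, x]
            ts = []
            for a in range(3):
                if abs(d[a]) < 1e-15:
                    if not (lo[a] <= o[a] <= hi[a]):
                        ts = None
                        break
                else:
                    ts.append(((lo[a] - o[a]) / d[a], (hi[a] - o[a]) / d[a]))
            if ts is None:
                continue
            near = max(min(a, b) for a, b in ts) if ts else -np.inf
            far = min(max(a, b) for a, b in ts) if ts else np.inf
            if far < near:
                continue
            s = max(near, 0.0)
            while s <= far:
                pos = o + s * d
                idx = np.floor(pos + 0.5).astype(int)
                if (
                    0 <= idx[0] < n_u
                    and 0 <= idx[1] < n_v
                    and 0 <= idx[2] < T
                    and stc.grid[idx[1], idx[0], idx[2]] != 0
                ):
                    hits[y, x] = (idx[1], idx[0], idx[2])
                    break
                s += step
    return hits


class TestComputeNormals:
    def test_uniform_background_all_zero(self):
        stc = make_stc(np.zeros((6, 6, 6)))
        nf = compute_normals(stc)
        assert np.all(nf.vectors == 0)

    def test_half_space_boundary_normals_along_axis(self):
        grid = np.zeros((8, 8, 8))
        grid[:, :, :4] = 1  # occupied for k <= 3
        nf = compute_normals(make_stc(grid), smooth_sigma=0.0)
        # at the step, the outward normal is exactly +-(0, 0, 1)
        interior = nf.vectors[2:6, 2:6, 3]
        assert np.allclose(np.abs(interior[:, :, 2]), 1.0)
        assert np.allclose(interior[:, :, :2], 0.0)

    def test_unit_length_or_zero(self):
        rng = np.random.default_rng(0)
        stc = make_stc(rng.integers(0, 3, size=(10, 10, 10)))
        nf = compute_normals(stc)
        norms = np.linalg.norm(nf.vectors, axis=-1)
        assert np.all((norms < 1e-9) | (np.abs(norms - 1) < 1e-6))

    def test_cylinder_membrane_normals_are_radial(self):
        ds = sphere_dataset(radius=1.0, subdivisions=3, oid=1, n_times=10)
        stc = build_stc(ds, MEDIAN_PLANE, resolution=(64, 64), mode="filled")
        nf = compute_normals(stc)
        n_v, n_u, T = stc.shape
        jj, ii, kk = np.nonzero(np.linalg.norm(nf.vectors, axis=-1) > 0.5)
        away = (kk >= 2) & (kk <= T - 3)
        jj, ii, kk = jj[away], ii[away], kk[away]
        assert len(jj) > 100
        cu, cv = (n_u - 1) / 2, (n_v - 1) / 2
        radial = np.stack([ii - cu, jj - cv, np.zeros_like(kk)], axis=1).astype(float)
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        n = nf.vectors[jj, ii, kk]
        align = np.abs(np.einsum("pk,pk->p", n, radial))
        assert np.mean(align > 0.9) > 0.95

    def test_normals_flip_under_occupancy_complement(self):
        rng = np.random.default_rng(1)
        grid = (rng.random((12, 12, 12)) < 0.4).astype(np.uint32)
        comp = (grid == 0).astype(np.uint32)
        a = compute_normals(make_stc(grid), smooth_sigma=0.0).vectors
        b = compute_normals(make_stc(comp), smooth_sigma=0.0).vectors
        interior = np.ones(grid.shape, bool)
        interior[[0, -1], :, :] = interior[:, [0, -1], :] = interior[:, :, [0, -1]] = False
        defined = (np.linalg.norm(a, axis=-1) > 0.5) & (np.linalg.norm(b, axis=-1) > 0.5) & interior
        assert defined.any()
        assert np.allclose(a[defined], -b[defined], atol=1e-9)


class TestValueLookup:
    def make_annotations(self):
        ann = AnnotationTable()
        ann.set("volume", 1, 0, 10.0)
        ann.set("volume", 2, 0, 30.0)
        ann.set("fate", 1, 0, "neural")
        return ann

    def test_endpoint_values_map_to_colormap_endpoints(self):
        from matplotlib import colormaps

        lk = build_lookup(self.make_annotations(), "volume", colormap="viridis")
        assert np.allclose(lk.color(1, 0), colormaps["viridis"](0.0)[:3])
        assert np.allclose(lk.color(2, 0), colormaps["viridis"](1.0)[:3])

    def test_missing_entry_maps_to_sentinel_gray(self):
        lk = build_lookup(self.make_annotations(), "volume")
        assert np.allclose(lk.color(99, 5), [0.5, 0.5, 0.5])

    def test_categorical_palette_is_stable(self):
        lk1 = build_lookup(self.make_annotations(), "fate")
        lk2 = build_lookup(self.make_annotations(), "fate")
        assert lk1.categorical
        assert np.allclose(lk1.color(1, 0), lk2.color(1, 0))

    def test_switching_property_leaves_volume_and_normals_untouched(self):
        ds = sphere_dataset(radius=1.0, subdivisions=2, n_times=2)
        stc = build_stc(ds, MEDIAN_PLANE, resolution=(32, 32))
        nf = compute_normals(stc)
        grid_hash = hash(stc.grid.tobytes())
        normals_hash = hash(nf.vectors.tobytes())
        build_lookup(self.make_annotations(), "volume")
        build_lookup(self.make_annotations(), "fate")
        assert hash(stc.grid.tobytes()) == grid_hash
        assert hash(nf.vectors.tobytes()) == normals_hash

    def test_unknown_property_raises(self):
        from sthcube import NotFoundError

        with pytest.raises(NotFoundError):
            build_lookup(self.make_annotations(), "pressure")


class TestRaycast:
    def test_empty_volume_renders_background(self):
        stc = make_stc(np.zeros((8, 8, 8)))
        nf = compute_normals(stc)
        img = render_stc(stc, nf, None, RenderSettings(background=(0.1, 0.2, 0.3)))
        assert np.allclose(img, [0.1, 0.2, 0.3])

    def test_single_voxel_headon_shading(self):
        # normal facing the light head-on, ks = 0: pixel = (ka + kd) * C
        grid = np.zeros((5, 5, 5))
        grid[2, 2, 2] = 1
        stc = make_stc(grid)
        vectors = np.zeros((5, 5, 5, 3))
        vectors[2, 2, 2] = [0.0, 0.0, 1.0]
        nf = NormalField(vectors=vectors)
        settings = RenderSettings(view_dir=(0, 0, -1), light_pos=(2, 2, 100), ks=0.0)
        img, hits = render_stc(stc, nf, None, settings, return_hits=True)
        hit_px = np.argwhere(hits[:, :, 0] >= 0)
        assert len(hit_px) == 1
        y, x = hit_px[0]
        expected = np.clip((settings.ka + settings.kd) * 0.8, 0, 1)
        assert np.allclose(img[y, x], expected)

    def test_first_hit_matches_brute_force_on_random_volume(self):
        rng = np.random.default_rng(123)
        grid = rng.integers(0, 4, size=(16, 16, 16))
        stc = make_stc(grid)
        settings = RenderSettings(view_dir=(0, 0, -1))
        fast = raycast_first_hit(stc, settings)
        slow = brute_force_first_hits(stc, settings, step=0.25)
        assert np.array_equal(fast, slow)

    def test_opacity_mutating_behind_first_hit_leaves_image_unchanged(self):
        rng = np.random.default_rng(5)
        grid = rng.integers(0, 3, size=(12, 12, 12))
        stc = make_stc(grid)
        nf = compute_normals(stc)
        settings = RenderSettings(view_dir=(0, 0, -1))
        img, hits = render_stc(stc, nf, None, settings, return_hits=True)
        # zero every voxel strictly behind a first hit along the -k rays
        mutated = grid.copy()
        for y, x in np.argwhere(hits[:, :, 0] >= 0):
            j, i, k = hits[y, x]
            mutated[j, i, :k] = (mutated[j, i, :k] + 1) % 4
        stc2 = stc.with_grid(mutated.astype(np.uint32))
        img2 = render_stc(stc2, nf, None, settings)
        assert np.array_equal(img, img2)

    def test_moving_light_changes_shading_not_hits(self):
        ds = sphere_dataset(radius=1.0, subdivisions=3, n_times=6)
        stc = build_stc(ds, MEDIAN_PLANE, resolution=(32, 32), mode="filled")
        nf = compute_normals(stc)
        s1 = RenderSettings(view_dir=(0.3, 0.2, -1), light_pos=(-40, -40, 100))
        s2 = RenderSettings(view_dir=(0.3, 0.2, -1), light_pos=(60, 10, -80))
        img1, h1 = render_stc(stc, nf, None, s1, return_hits=True)
        img2, h2 = render_stc(stc, nf, None, s2, return_hits=True)
        assert np.array_equal(h1, h2)
        assert not np.array_equal(img1, img2)

    def test_degenerate_camera_rejected(self):
        with pytest.raises(ValidationError):
            RenderSettings(view_dir=(0, 0, 0))

    def test_coefficient_guard(self):
        with pytest.raises(ValidationError):
            RenderSettings(ka=0.9, kd=0.9)
        RenderSettings(ka=0.9, kd=0.9, unsafe_coefficients=True)


class TestCut:
    def test_plane_beyond_volume_keeps_everything(self):
        rng = np.random.default_rng(2)
        stc = make_stc(rng.integers(0, 3, size=(10, 10, 10)))
        out = cut_stc(stc, CutSpec(point=[100, 0, 0], normal=[-1, 0, 0], keep_side=1))
        assert out.grid.tobytes() == stc.grid.tobytes()

    def test_time_cut_zeroes_later_slices(self):
        grid = np.ones((6, 6, 10))
        stc = make_stc(grid)
        K = 4
        out = cut_stc(stc, CutSpec(point=[0, 0, K], normal=[0, 0, -1], keep_side=1))
        assert np.all(out.grid[:, :, : K + 1] == 1)
        assert np.all(out.grid[:, :, K + 1 :] == 0)

    def test_oblique_cut_matches_per_voxel_signed_distance(self):
        rng = np.random.default_rng(3)
        grid = rng.integers(0, 4, size=(9, 11, 7))
        stc = make_stc(grid)
        cut = CutSpec(point=[4.3, 5.1, 2.7], normal=[0.5, -0.3, 0.8], keep_side=-1)
        out = cut_stc(stc, cut)
        p, n = np.array(cut.point), np.array(cut.normal)
        for j in range(9):
            for i in range(11):
                for k in range(7):
                    s = (np.array([i, j, k], float) - p) @ n
                    expect = grid[j, i, k] if s * cut.keep_side >= 0 else 0
                    assert out.grid[j, i, k] == expect

    def test_cut_idempotent_and_complement_partitions(self):
        rng = np.random.default_rng(4)
        stc = make_stc(rng.integers(0, 3, size=(8, 8, 8)))
        cut = CutSpec(point=[3.37, 4.11, 3.95], normal=[0.2, 0.7, -0.4], keep_side=1)
        comp = CutSpec(point=cut.point, normal=cut.normal, keep_side=-1)
        once = cut_stc(stc, cut)
        twice = cut_stc(once, cut)
        assert once.grid.tobytes() == twice.grid.tobytes()
        other = cut_stc(stc, comp)
        nz = stc.grid != 0
        nz1 = once.grid != 0
        nz2 = other.grid != 0
        assert np.array_equal(nz1 | nz2, nz)
        assert not (nz1 & nz2).any()  # generic plane: no voxel exactly on it


class TestQueryVoxel:
    def test_root_cell_record(self, small_embryo):
        _, dataset, lineage, ann = small_embryo
        stc = build_stc(dataset, MEDIAN_PLANE, resolution=(48, 48), mode="filled")
        lookup = build_lookup(ann, "volume")
        jj, ii = np.nonzero(stc.grid[:, :, 0] == 1)
        rec = query_voxel(stc, lookup, lineage, ann, (ii[0], jj[0], 0))
        assert rec["id"] == 1
        assert rec["time"] == 0
        assert rec["value"] == pytest.approx(ann.get("volume", 1, 0))
        assert rec["children"] == [2, 3]
        assert rec["parent"] is None

    def test_background_voxel_record(self):
        stc = make_stc(np.zeros((4, 4, 4)))
        rec = query_voxel(stc, None, None, None, (0, 0, 2))
        assert rec["background"] is True
        assert rec["time"] == 2

    def test_slice_time_passthrough(self, small_embryo):
        _, dataset, _, _ = small_embryo
        stc = build_stc(dataset, MEDIAN_PLANE, resolution=(32, 32))
        rec = query_voxel(stc, None, None, None, (0, 0, 7))
        assert rec["time"] == stc.times[7]

    def test_out_of_bounds_rejected(self):
        stc = make_stc(np.zeros((4, 4, 4)))
        with pytest.raises(ValidationError):
            query_voxel(stc, None, None, None, (0, 0, 9))
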