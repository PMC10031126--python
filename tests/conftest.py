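import numpy as np
import pytest
import trimesh

from sthcube import (
    CameraFrame,
    LabeledObject,
    STCVolume,
    SimulationParams,
    TemporalDataset,
    define_plane,
    simulate,
)

MEDIAN_PLANE = define_plane([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0])


def sphere_dataset(radius=1.0, subdivisions=4, oid=7, n_times=1, offset=(0, 0, 0)):
    """Dataset of one static sphere repeated over n_times frames."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh.apply_translation(offset)
    return TemporalDataset([[LabeledObject(id=oid, mesh=mesh)] for _ in range(n_times)])


def make_stc(grid, pixel_size=1.0):
    """Wrap a raw label grid (n_v, n_u, T) into an STCVolume with a dummy frame."""
    grid = np.asarray(grid, dtype=np.uint32)
    n_v, n_u, T = grid.shape
    frame = CameraFrame(
        origin=np.zeros(3),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 1.0, 0.0]),
        width=float(n_u * pixel_size),
        height=float(n_v * pixel_size),
        resolution=(n_u, n_v),
        eps=pixel_size,
    )
    return STCVolume(grid=grid, plane=MEDIAN_PLANE, frame=frame, mode="membrane", times=tuple(range(T)))


@pytest.fixture(scope="session")
def small_embryo():
    """One root cell through two division rounds: 1 -> 2 -> 4 cells."""
    params = SimulationParams(
        n_initial_cells=1, n_timesteps=14, division_period=6, jitter_sigma=0.3, seed=11
    )
    dataset, lineage, annotations = simulate(params)
    return params, dataset, lineage, annotations


@pytest.fixture(scope="session")
def async_embryo():
    """Two roots, one of which skips a division round."""
    params = SimulationParams(
        n_initial_cells=2,
        n_timesteps=16,
        division_period=6,
        asynchrony_set=frozenset({2}),
        jitter_sigma=0.3,
        seed=5,
    )
    dataset, lineage, annotations = simulate(params)
    return params, dataset, lineage, annotations
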