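"""Seeded generator of an embryo-like time series of dividing labeled cells.

The generator emulates the statistical structure of a light-sheet recording
of early embryonic development after segmentation and meshing: a few tens of
closed, convex-ish cells packed inside an ellipsoid, small inter-frame
motion, synchronous "waves" of binary divisions with optional asynchronous
branches, a consistent lineage tree, and per-(cell, time) annotations for
cell volume and remaining lifespan (frames until the next division).

It is not a biophysical model: there is no mechanics, no adhesion, no
realistic cell shapes.  Its purpose is to provide a fully deterministic,
ground-truth-complete input for the projection, rendering and filtering
stages.

Conventions
-----------
* a cell born at frame ``t_b`` with cycle length ``c`` lives over the
  inclusive interval ``[t_b, t_b + c - 1]`` and its two daughters are born
  at ``t_b + c`` (if that frame exists; otherwise the cell simply persists
  to the last frame);
* cells listed in ``asynchrony_set`` skip exactly one division round: their
  cycle is ``2 * division_period`` instead of ``division_period``;
* daughters have radius ``parent_radius * 2**(-1/3)`` so the summed volume
  is conserved, and are placed at ``parent_center ± axis * r_daughter / 2``
  along a random unit axis — the pair is displaced apart by one daughter
  radius in total, so the daughters stay adjacent and overlap slightly,
  the way abutting cells do in real dense segmentations;
* ``remaining_lifespan`` at frame t is ``t_last - t``: it decreases by one
  per frame and reaches 0 at the cell's last frame.  For cells whose next
  division falls outside the simulated window it counts frames to the end
  of their track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .core import (
    AnnotationTable,
    LabeledObject,
    LineageNode,
    LineageTree,
    TemporalDataset,
    ValidationError,
)

# Embryo envelope: ellipsoid semi-axes in world units (think micrometres for
# an ascidian-sized embryo).  The envelope is fixed; cells shrink as they
# divide, as in real cleavage-stage development where total volume is
# roughly conserved.
ELLIPSOID_SEMI_AXES = np.array([90.0, 75.0, 65.0])

# Fraction of the ellipsoid volume occupied by cells at t=0.
_PACKING_FRACTION = 0.9

# Relative per-vertex radial perturbation applied to each cell's sphere so
# that no two cells are exactly congruent.
_SHAPE_NOISE = 0.02

# Frames over which the cavity deformation ramps up after its onset.
_CAVITY_RAMP_FRAMES = 5

_ICOSPHERE_SUBDIV = 2
_HALF_CUBE_ROOT = 2.0 ** (-1.0 / 3.0)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic embryo.

    Parameters
    ----------
    n_initial_cells
        Number of root cells at frame 0.
    n_timesteps
        Number of frames T; frames are 0..T-1.
    division_period
        Cycle length p in frames; every non-asynchronous cell divides every
        p frames.
    asynchrony_set
        Ids of cells that skip exactly one division round (their cycle is
        2p).  Root cells have ids 1..n_initial_cells; later ids are assigned
        in division order.
    jitter_sigma
        Scale (world units) of the random per-frame centroid displacement;
        the displacement magnitude is |N(0, jitter_sigma)| along a uniform
        random direction, so it stays below 3*jitter_sigma for ~99.7% of
        frames — small compared to a cell radius, as in real recordings
        where inter-frame motion is well below cell size.
    deformation
        Optional ``(amplitude, onset_frame)``: from the onset on, cells are
        displaced radially away from the embryo center with a Gaussian
        radial profile, ramping up over a few frames — a crude cavity, the
        kind of shape change gastrulation produces.  Amplitude in world
        units.
    seed
        Single seed from which all randomness (placement, division axes,
        jitter, shape noise) flows.
    """

    n_initial_cells: int = 8
    n_timesteps: int = 20
    division_period: int = 8
    asynchrony_set: frozenset[int] = field(default_factory=frozenset)
    jitter_sigma: float = 1.0
    deformation: tuple[float, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_initial_cells < 1:
            raise ValidationError("n_initial_cells must be >= 1")
        if self.n_timesteps < 1:
            raise ValidationError("n_timesteps must be >= 1")
        if self.division_period < 1:
            raise ValidationError("division_period must be >= 1")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be >= 0")
        if self.deformation is not None:
            amp, onset = self.deformation
            if amp < 0:
                raise ValidationError("deformation amplitude must be >= 0")
        object.__setattr__(self, "asynchrony_set", frozenset(int(i) for i in self.asynchrony_set))


@dataclass
class _Cell:
    id: int
    parent: int | None
    t_birth: int
    radius: float
    center: np.ndarray  # current center, mutated frame by frame
    cycle: int
    t_div: int | None  # frame at which daughters are born, None if never
    t_last: int


def _root_radius(n_initial: int) -> float:
    a, b, c = ELLIPSOID_SEMI_AXES
    per_cell = _PACKING_FRACTION * a * b * c / n_initial
    return float(per_cell ** (1.0 / 3.0))


def _place_roots(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded dart-throwing placement inside the ellipsoid, recentred on 0."""
    if n == 1:
        return np.zeros((1, 3))
    semi = np.maximum(ELLIPSOID_SEMI_AXES - 0.5 * radius, 0.3 * ELLIPSOID_SEMI_AXES)
    centers: list[np.ndarray] = []
    min_sep = 1.2 * radius
    for _ in range(n):
        best = None
        for _attempt in range(200):
            p = rng.uniform(-1.0, 1.0, 3) * semi
            if np.sum((p / semi) ** 2) > 1.0:
                continue
            if all(np.linalg.norm(p - q) >= min_sep for q in centers):
                best = p
                break
            if best is None:
                best = p  # fallback: accept overlap after enough tries
        centers.append(best)
    pts = np.array(centers)
    return pts - pts.mean(axis=0)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _cavity_displacement(centers: np.ndarray, t: int, deformation: tuple[float, int] | None) -> np.ndarray:
    if deformation is None:
        return np.zeros_like(centers)
    amplitude, onset = deformation
    if t < onset or amplitude == 0:
        return np.zeros_like(centers)
    ramp = min(1.0, (t - onset + 1) / _CAVITY_RAMP_FRAMES)
    r_cav = 0.5 * float(ELLIPSOID_SEMI_AXES.min())
    d = np.linalg.norm(centers, axis=1)
    safe = np.maximum(d, 1e-9)
    profile = np.exp(-((d / r_cav) ** 2))
    return centers / safe[:, None] * (amplitude * ramp * profile)[:, None]


class _MeshFactory:
    """Builds each cell's mesh from a shared unit icosphere template.

    Every cell gets a fixed per-vertex radial perturbation drawn once from
    its id (and the master seed), so its shape is stable across frames and
    its daughters' summed volume matches the parent's to within the noise.
    """

    def __init__(self, seed: int):
        self._seed = seed
        tpl = trimesh.creation.icosphere(subdivisions=_ICOSPHERE_SUBDIV, radius=1.0)
        self._vertices = np.asarray(tpl.vertices)
        self._faces = np.asarray(tpl.faces)
        self._bumps: dict[int, np.ndarray] = {}

    def _bump(self, cell_id: int) -> np.ndarray:
        if cell_id not in self._bumps:
            rng = np.random.default_rng([self._seed, cell_id, 7919])
            self._bumps[cell_id] = 1.0 + _SHAPE_NOISE * rng.standard_normal(len(self._vertices))
        return self._bumps[cell_id]

    def build(self, cell_id: int, radius: float, center: np.ndarray) -> trimesh.Trimesh:
        verts = self._vertices * (radius * self._bump(cell_id))[:, None] + center
        return trimesh.Trimesh(vertices=verts, faces=self._faces.copy(), process=False)


def simulate(params: SimulationParams) -> tuple[TemporalDataset, LineageTree, AnnotationTable]:
    """Run the synthetic embryo and return dataset, lineage and annotations.

    Identical ``params`` (including the seed) produce bit-identical output.
    The returned lineage always validates cleanly against the dataset, and
    the annotation table carries ``volume`` (world units cubed, measured on
    the actual meshes) and ``remaining_lifespan`` (frames) for every
    (id, t) instance.
    """
    rng = np.random.default_rng(params.seed)
    T = params.n_timesteps
    p = params.division_period

    r0 = _root_radius(params.n_initial_cells)
    root_centers = _place_roots(params.n_initial_cells, r0, rng)

    def cycle_of(cid: int) -> int:
        return 2 * p if cid in params.asynchrony_set else p

    def schedule(cid: int, t_birth: int) -> tuple[int | None, int]:
        t_div = t_birth + cycle_of(cid)
        if t_div <= T - 1:
            return t_div, t_div - 1
        return None, T - 1

    cells: dict[int, _Cell] = {}
    for i in range(params.n_initial_cells):
        cid = i + 1
        t_div, t_last = schedule(cid, 0)
        cells[cid] = _Cell(cid, None, 0, r0, root_centers[i].copy(), cycle_of(cid), t_div, t_last)
    next_id = params.n_initial_cells + 1

    factory = _MeshFactory(params.seed)
    frames: list[list[LabeledObject]] = []
    annotations = AnnotationTable()
    alive: list[_Cell] = sorted(cells.values(), key=lambda c: c.id)

    for t in range(T):
        if t > 0:
            # divisions whose daughters are born at this frame
            still, born = [], []
            for cell in alive:
                if cell.t_div == t:
                    r_d = cell.radius * _HALF_CUBE_ROOT
                    axis = _random_unit(rng)
                    for sgn in (+1.0, -1.0):
                        cid = next_id
                        next_id += 1
                        t_div, t_last = schedule(cid, t)
                        child = _Cell(
                            cid,
                            cell.id,
                            t,
                            r_d,
                            cell.center + sgn * 0.5 * r_d * axis,
                            cycle_of(cid),
                            t_div,
                            t_last,
                        )
                        cells[cid] = child
                        born.append(child)
                else:
                    still.append(cell)
            alive = sorted(still + born, key=lambda c: c.id)
            # per-frame centroid jitter, magnitude |N(0, sigma)|
            if params.jitter_sigma > 0:
                for cell in alive:
                    step = abs(rng.normal(0.0, params.jitter_sigma))
                    cell.center = cell.center + step * _random_unit(rng)

        centers = np.array([c.center for c in alive])
        disp = _cavity_displacement(centers, t, params.deformation)
        objs: list[LabeledObject] = []
        for cell, d in zip(alive, disp):
            mesh = factory.build(cell.id, cell.radius, cell.center + d)
            objs.append(LabeledObject(id=cell.id, mesh=mesh))
            annotations.set("volume", cell.id, t, float(mesh.volume))
            annotations.set("remaining_lifespan", cell.id, t, int(cell.t_last - t))
        frames.append(objs)

    dataset = TemporalDataset(frames)
    lineage = LineageTree(
        [LineageNode(c.id, c.t_birth, c.t_last, c.parent) for c in sorted(cells.values(), key=lambda c: c.id)]
    )
    return dataset, lineage, annotations
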