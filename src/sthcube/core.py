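"""Shared domain types: temporal dataset, lineage tree, annotations, filter state.

Conventions used throughout the package:

* time is a contiguous integer frame index 0..T-1;
* object identifiers are positive integers, 0 is reserved for background
  (this is what makes label-volume encodings possible);
* lineage life intervals ``[t_birth, t_last]`` are inclusive on both ends.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

try:  # trimesh is required, but keep the import local to geometry users
    import trimesh
except ImportError:  # pragma: no cover
    trimesh = None


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class NotFoundError(KeyError):
    """Raised when an object id, property or time index does not exist."""


# ---------------------------------------------------------------------------
# Geometry carriers
# ---------------------------------------------------------------------------

@dataclass
class LabelVolumeFrame:
    """A labeled voxel grid for one time point.

    ``labels[i, j, k]`` is the object id at voxel (i, j, k); world position of
    a voxel center is ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
    """

    labels: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label volume must have an integer dtype")
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValidationError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be positive")

    def ids(self) -> set[int]:
        u = np.unique(self.labels)
        return {int(x) for x in u if x != 0}

    def bounds(self) -> np.ndarray:
        lo = self.origin
        hi = self.origin + self.spacing * np.array(self.labels.shape)
        return np.stack([lo, hi])

    def sample_nearest(self, points: np.ndarray) -> np.ndarray:
        """Nearest-neighbor label at each world point (0 outside the grid)."""
        pts = np.asarray(points, dtype=float)
        idx = np.floor((pts - self.origin) / self.spacing).astype(int)
        shape = np.array(self.labels.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(pts), dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass
class LabeledObject:
    """One object (a cell, in the embryo use case) at one time point.

    Geometry is either a closed triangle mesh (``mesh``) or a reference to a
    shared labeled voxel grid (``voxels``), in which case the object occupies
    the voxels carrying its id.
    """

    id: int
    mesh: "trimesh.Trimesh | None" = None
    voxels: LabelVolumeFrame | None = None

    def __post_init__(self) -> None:
        if int(self.id) <= 0:
            raise ValidationError(f"object id must be a positive integer, got {self.id}")
        self.id = int(self.id)
        if (self.mesh is None) == (self.voxels is None):
            raise ValidationError("exactly one of mesh or voxels must be given")
        if self.mesh is not None and not np.all(np.isfinite(self.mesh.vertices)):
            raise ValidationError(f"object {self.id}: non-finite vertex coordinates")

    @property
    def is_mesh(self) -> bool:
        return self.mesh is not None

    def bounds(self) -> np.ndarray:
        if self.mesh is not None:
            return np.array(self.mesh.bounds)
        return self.voxels.bounds()


class TemporalDataset:
    """Ordered time series of labeled objects.

    Parameters
    ----------
    frames
        List indexed by time; element t is the list of :class:`LabeledObject`
        present at frame t.  Time indices are implicitly 0..T-1.
    """

    def __init__(self, frames: Iterable[Iterable[LabeledObject]]):
        self._frames: list[list[LabeledObject]] = [list(f) for f in frames]
        if len(self._frames) == 0:
            raise ValidationError("dataset must contain at least one time step")
        for t, objs in enumerate(self._frames):
            seen: set[int] = set()
            for o in objs:
                if o.id in seen:
                    raise ValidationError(f"duplicate object id {o.id} at t={t}")
                seen.add(o.id)

    @property
    def n_times(self) -> int:
        return len(self._frames)

    @property
    def times(self) -> list[int]:
        return list(range(len(self._frames)))

    def objects(self, t: int) -> list[LabeledObject]:
        if not 0 <= t < len(self._frames):
            raise NotFoundError(f"time index {t} out of range [0, {len(self._frames) - 1}]")
        return self._frames[t]

    def ids_at(self, t: int) -> set[int]:
        return {o.id for o in self.objects(t)}

    def instances(self) -> Iterable[tuple[int, int]]:
        """Yield every (object id, time) pair present in the dataset."""
        for t, objs in enumerate(self._frames):
            for o in objs:
                yield o.id, t

    @property
    def world_bounds(self) -> np.ndarray:
        """Axis-aligned bounding box over all objects and times, shape (2, 3)."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for objs in self._frames:
            for o in objs:
                b = o.bounds()
                lo = np.minimum(lo, b[0])
                hi = np.maximum(hi, b[1])
        if not np.all(np.isfinite(lo)):
            raise ValidationError("dataset contains no geometry")
        return np.stack([lo, hi])

    def check_watertight(self) -> list[int]:
        """Return ids of mesh objects (any frame) that fail the watertight test."""
        bad = []
        for t, objs in enumerate(self._frames):
            for o in objs:
                if o.is_mesh and not o.mesh.is_watertight:
                    bad.append(o.id)
        return sorted(set(bad))


# ---------------------------------------------------------------------------
# Lineage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageNode:
    id: int
    t_birth: int
    t_last: int
    parent: int | None


class LineageTree:
    """Genealogy of object ids: life intervals plus parent→child edges.

    Each node lives over the inclusive frame interval ``[t_birth, t_last]``;
    a division is represented by child nodes whose ``t_birth`` is strictly
    after the parent's ``t_last``.
    """

    def __init__(
        self,
        nodes: Iterable[LineageNode] | Mapping[int, tuple[int, int, int | None]],
        strict: bool = True,
    ):
        """``strict=True`` (the default) rejects parent/child interval
        ordering violations outright; ``strict=False`` admits them so that
        dubious external data can be loaded and then audited with
        :func:`validate_lineage`."""
        if isinstance(nodes, Mapping):
            nodes = [LineageNode(i, b, l, p) for i, (b, l, p) in nodes.items()]
        self._nodes: dict[int, LineageNode] = {}
        for n in nodes:
            if n.id <= 0:
                raise ValidationError(f"lineage id must be positive, got {n.id}")
            if n.id in self._nodes:
                raise ValidationError(f"duplicate lineage id {n.id}")
            if n.t_birth > n.t_last:
                raise ValidationError(f"node {n.id}: t_birth {n.t_birth} > t_last {n.t_last}")
            self._nodes[n.id] = n
        self._children: dict[int, list[int]] = {i: [] for i in self._nodes}
        for n in self._nodes.values():
            if n.parent is not None:
                if n.parent not in self._nodes:
                    raise ValidationError(f"node {n.id}: unknown parent {n.parent}")
                self._children[n.parent].append(n.id)
        for cs in self._children.values():
            cs.sort()
        self._check_acyclic()
        if strict:
            for n in self._nodes.values():
                if n.parent is not None and self._nodes[n.parent].t_last >= n.t_birth:
                    raise ValidationError(
                        f"parent {n.parent} t_last >= t_birth of child {n.id}"
                    )

    def _check_acyclic(self) -> None:
        for start in self._nodes:
            seen = set()
            cur: int | None = start
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"lineage contains a cycle through id {start}")
                seen.add(cur)
                cur = self._nodes[cur].parent

    # -- access ------------------------------------------------------------

    def __contains__(self, oid: int) -> bool:
        return oid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def ids(self) -> list[int]:
        return sorted(self._nodes)

    def node(self, oid: int) -> LineageNode:
        if oid not in self._nodes:
            raise NotFoundError(f"unknown object id {oid}")
        return self._nodes[oid]

    def interval(self, oid: int) -> tuple[int, int]:
        n = self.node(oid)
        return n.t_birth, n.t_last

    def parent(self, oid: int) -> int | None:
        return self.node(oid).parent

    def children(self, oid: int) -> list[int]:
        if oid not in self._nodes:
            raise NotFoundError(f"unknown object id {oid}")
        return list(self._children[oid])

    def roots(self) -> list[int]:
        return sorted(i for i, n in self._nodes.items() if n.parent is None)

    def descendants(self, oid: int) -> set[int]:
        """All ids reachable from ``oid`` through child edges, excluding ``oid``."""
        out: set[int] = set()
        stack = list(self._children.get(oid, []))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self._children[c])
        return out

    # -- CSV round trip ----------------------------------------------------
    # header: id,parent_id,t_birth,t_last ; parent_id empty for roots

    def to_csv(self, path) -> None:
        rows = [
            {
                "id": n.id,
                "parent_id": "" if n.parent is None else n.parent,
                "t_birth": n.t_birth,
                "t_last": n.t_last,
            }
            for n in sorted(self._nodes.values(), key=lambda n: n.id)
        ]
        pd.DataFrame(rows, columns=["id", "parent_id", "t_birth", "t_last"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "LineageTree":
        df = pd.read_csv(path, dtype={"id": int, "t_birth": int, "t_last": int})
        nodes = []
        for _, row in df.iterrows():
            p = row["parent_id"]
            parent = None if pd.isna(p) or p == "" else int(p)
            nodes.append(LineageNode(int(row["id"]), int(row["t_birth"]), int(row["t_last"]), parent))
        # external files may be inconsistent; load them and let
        # validate_lineage report the problems
        return cls(nodes, strict=False)


def propagate_selection(lineage: LineageTree, seed: tuple[int, int]) -> set[int]:
    """Return the seed id plus the ids of all its descendants.

    This is the propagation rule used by object highlighting/hiding: a state
    change at one (id, t) instance applies to every temporal instance of the
    id and of all objects descended from it (children after each division,
    transitively).  Ancestors are not affected.

    Parameters
    ----------
    seed
        ``(object id, time index)``; the time must lie inside the id's life
        interval.
    """
    oid, t = seed
    node = lineage.node(oid)  # raises NotFoundError for unknown ids
    if not node.t_birth <= t <= node.t_last:
        raise ValidationError(
            f"time {t} outside life interval [{node.t_birth}, {node.t_last}] of id {oid}"
        )
    return {oid} | lineage.descendants(oid)


@dataclass
class LineageReport:
    """Outcome of :func:`validate_lineage`; empty iff dataset and lineage agree."""

    missing_in_lineage: list[tuple[int, int]] = field(default_factory=list)
    outside_interval: list[tuple[int, int]] = field(default_factory=list)
    missing_in_dataset: list[tuple[int, int]] = field(default_factory=list)
    ordering_violations: list[tuple[int, int]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.missing_in_lineage
            or self.outside_interval
            or self.missing_in_dataset
            or self.ordering_violations
        )

    def summary(self) -> str:
        buf = _io.StringIO()
        if self.is_empty():
            buf.write("lineage and dataset are consistent\n")
        for oid, t in self.missing_in_lineage:
            buf.write(f"instance (id={oid}, t={t}) present in dataset but id missing from lineage\n")
        for oid, t in self.outside_interval:
            buf.write(f"instance (id={oid}, t={t}) outside its lineage life interval\n")
        for oid, t in self.missing_in_dataset:
            buf.write(f"lineage expects (id={oid}, t={t}) but it is absent from the dataset\n")
        for p, c in self.ordering_violations:
            buf.write(f"parent {p} has t_last >= t_birth of child {c}\n")
        return buf.getvalue()


def validate_lineage(lineage: LineageTree, dataset: TemporalDataset) -> LineageReport:
    """Cross-check a dataset against a lineage tree.

    Reports every (id, t) instance present in the dataset but absent from or
    outside its life interval in the lineage, every (id, t) the lineage
    promises but the dataset lacks, and every parent/child interval-ordering
    violation.  An empty report means the two agree exactly.
    """
    report = LineageReport()
    present: set[tuple[int, int]] = set()
    for oid, t in dataset.instances():
        present.add((oid, t))
        if oid not in lineage:
            report.missing_in_lineage.append((oid, t))
        else:
            b, l = lineage.interval(oid)
            if not b <= t <= l:
                report.outside_interval.append((oid, t))
    T = dataset.n_times
    for oid in lineage.ids:
        b, l = lineage.interval(oid)
        for t in range(max(b, 0), min(l, T - 1) + 1):
            if (oid, t) not in present:
                report.missing_in_dataset.append((oid, t))
        p = lineage.parent(oid)
        if p is not None and lineage.interval(p)[1] >= b:
            report.ordering_violations.append((p, oid))
    report.missing_in_lineage.sort()
    report.outside_interval.sort()
    report.missing_in_dataset.sort()
    report.ordering_violations.sort()
    return report


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

class AnnotationTable:
    """Per-(object id, time) scalar or categorical annotations.

    Stored as ``property name -> {(id, t): value}``.  Missing entries are
    allowed; how a missing value is displayed is decided by the lookup in
    :mod:`sthcube.volume_shading` (a sentinel color).
    """

    def __init__(self, data: Mapping[str, Mapping[tuple[int, int], object]] | None = None):
        self._data: dict[str, dict[tuple[int, int], object]] = {}
        if data:
            for prop, table in data.items():
                self._data[str(prop)] = {(int(i), int(t)): v for (i, t), v in table.items()}

    @property
    def properties(self) -> list[str]:
        return sorted(self._data)

    def set(self, prop: str, oid: int, t: int, value) -> None:
        self._data.setdefault(prop, {})[(int(oid), int(t))] = value

    def get(self, prop: str, oid: int, t: int, default=None):
        if prop not in self._data:
            raise NotFoundError(f"unknown property {prop!r}")
        return self._data[prop].get((oid, t), default)

    def table(self, prop: str) -> dict[tuple[int, int], object]:
        if prop not in self._data:
            raise NotFoundError(f"unknown property {prop!r}")
        return dict(self._data[prop])

    # -- CSV round trip ----------------------------------------------------
    # long format, header: property,id,t,value

    def to_csv(self, path) -> None:
        rows = []
        for prop in sorted(self._data):
            for (oid, t), v in sorted(self._data[prop].items()):
                rows.append({"property": prop, "id": oid, "t": t, "value": v})
        pd.DataFrame(rows, columns=["property", "id", "t", "value"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path)
        out = cls()
        for _, row in df.iterrows():
            v = row["value"]
            # keep numbers numeric, everything else as category labels
            out.set(str(row["property"]), int(row["id"]), int(row["t"]), v)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for prop in sorted(self._data):
            for (oid, t), v in sorted(self._data[prop].items()):
                rows.append({"property": prop, "id": oid, "t": t, "value": v})
        return pd.DataFrame(rows, columns=["property", "id", "t", "value"])


# ---------------------------------------------------------------------------
# Filter state
# ---------------------------------------------------------------------------

OBJECT_STATES = ("normal", "highlighted", "hidden")


@dataclass(frozen=True)
class FilterState:
    """Shared filtering/selection state consumed by every view.

    ``value_range=None`` means "all" (no value filter); ``time_window=None``
    means the full time extent.  Ids absent from ``object_states`` are in the
    "normal" state.  ``current_time`` is the time cursor shown by preview
    renderings.
    """

    value_range: tuple[float, float] | None = None
    time_window: tuple[int, int] | None = None
    object_states: Mapping[int, str] = field(default_factory=dict)
    current_time: int = 0

    def __post_init__(self) -> None:
        if self.value_range is not None:
            lo, hi = self.value_range
            if lo > hi:
                raise ValidationError(f"value range lo {lo} > hi {hi}")
        if self.time_window is not None:
            t0, t1 = self.time_window
            if not (0 <= t0 <= t1):
                raise ValidationError(f"invalid time window [{t0}, {t1}]")
        for oid, st in dict(self.object_states).items():
            if st not in OBJECT_STATES:
                raise ValidationError(f"unknown object state {st!r} for id {oid}")
        object.__setattr__(self, "object_states", dict(self.object_states))

    def state_of(self, oid: int) -> str:
        return self.object_states.get(oid, "normal")

    def hidden_ids(self) -> set[int]:
        return {i for i, s in self.object_states.items() if s == "hidden"}

    def highlighted_ids(self) -> set[int]:
        return {i for i, s in self.object_states.items() if s == "highlighted"}

    def with_(self, **kw) -> "FilterState":
        return replace(self, **kw)
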