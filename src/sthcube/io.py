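"""Readers and writers for every on-disk format the package uses.

* datasets: a directory of per-(object, time) PLY/OBJ meshes — or one
  multi-page TIFF / NRRD label volume per time point — described by a JSON
  manifest that maps each file to its (id, t);
* STC volumes: multi-page TIFF (one page per time slice, 32-bit unsigned
  labels) or NRRD, with a JSON manifest next to the volume (same stem)
  recording plane, frame, eps, mode and times;
* lineage and annotations: the CSV formats defined on the core types;
* filter state and simulation parameters: YAML.

All writers are deterministic: no timestamps or other run-dependent bytes
go into any payload, so identical inputs produce identical files.

The NRRD support here is a deliberately minimal codec for the detached-free
raw-encoded subset of NRRD (little-endian, C-ordered), which is all this
package ever writes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import trimesh
import yaml

from .core import (
    AnnotationTable,
    LabeledObject,
    LabelVolumeFrame,
    LineageTree,
    TemporalDataset,
    ValidationError,
)
from .projection import CameraFrame, PlaneSpec, STCVolume
from .synthetic_embryo import SimulationParams
from .core import FilterState

MANIFEST_NAME = "manifest.json"

_NRRD_TYPES = {
    "uint8": np.uint8,
    "uint16": np.uint16,
    "uint32": np.uint32,
    "int16": np.int16,
    "int32": np.int32,
    "float": np.float32,
    "double": np.float64,
}
_NRRD_NAMES = {np.dtype(v): k for k, v in _NRRD_TYPES.items()}


# ---------------------------------------------------------------------------
# Minimal NRRD (raw encoding, little endian, C order)
# ---------------------------------------------------------------------------

def write_nrrd(path, array: np.ndarray) -> None:
    """Write an array as a raw-encoded NRRD file (attached header)."""
    arr = np.ascontiguousarray(array)
    dt = np.dtype(arr.dtype)
    if dt not in _NRRD_NAMES:
        raise ValidationError(f"unsupported NRRD dtype {dt}")
    # NRRD lists sizes fastest axis first; C order makes that the last axis
    sizes = " ".join(str(s) for s in arr.shape[::-1])
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_NAMES[dt]}\n"
        f"dimension: {arr.ndim}\n"
        f"sizes: {sizes}\n"
        "encoding: raw\n"
        "endian: little\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.astype(dt.newbyteorder("<")).tobytes())


def read_nrrd(path) -> np.ndarray:
    """Read a raw-encoded NRRD file written by :func:`write_nrrd`."""
    with open(path, "rb") as fh:
        blob = fh.read()
    end = blob.find(b"\n\n")
    if not blob.startswith(b"NRRD") or end < 0:
        raise ValidationError(f"{path}: not a supported NRRD file")
    fields: dict[str, str] = {}
    for line in blob[:end].decode("ascii").splitlines()[1:]:
        if ":" in line and not line.startswith("#"):
            k, v = line.split(":", 1)
            fields[k.strip()] = v.strip()
    if fields.get("encoding") != "raw":
        raise ValidationError(f"{path}: only raw-encoded NRRD is supported")
    dtype = np.dtype(_NRRD_TYPES[fields["type"]]).newbyteorder(
        "<" if fields.get("endian", "little") == "little" else ">"
    )
    sizes = [int(s) for s in fields["sizes"].split()]
    shape = tuple(sizes[::-1])
    data = np.frombuffer(blob[end + 2 :], dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise ValidationError(f"{path}: data size does not match header sizes")
    return data.reshape(shape).astype(dtype.newbyteorder("="))


# ---------------------------------------------------------------------------
# Dataset directory
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir,
    dataset: TemporalDataset,
    lineage: LineageTree | None = None,
    annotations: AnnotationTable | None = None,
) -> Path:
    """Write a dataset directory: meshes (ASCII PLY) or label volumes
    (multi-page TIFF, page = z), a JSON manifest, and optional lineage and
    annotation CSVs.  Returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    volume_entries = []
    written_volumes: dict[int, str] = {}
    for t in dataset.times:
        for obj in sorted(dataset.objects(t), key=lambda o: o.id):
            if obj.is_mesh:
                name = f"t{t:04d}_id{obj.id:06d}.ply"
                data = trimesh.exchange.ply.export_ply(obj.mesh, encoding="ascii")
                (out / name).write_bytes(data)
                entries.append({"t": t, "id": obj.id, "file": name})
            else:
                key = id(obj.voxels)
                if key not in written_volumes:
                    name = f"labels_t{t:04d}.tif"
                    # pages along the first axis
                    tifffile.imwrite(out / name, obj.voxels.labels, photometric="minisblack")
                    written_volumes[key] = name
                    volume_entries.append(
                        {
                            "t": t,
                            "file": name,
                            "origin": obj.voxels.origin.tolist(),
                            "spacing": obj.voxels.spacing.tolist(),
                        }
                    )
    manifest = {
        "format": "sthcube-dataset",
        "n_times": dataset.n_times,
        "meshes": entries,
        "label_volumes": volume_entries,
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if lineage is not None:
        lineage.to_csv(out / "lineage.csv")
    if annotations is not None:
        annotations.to_csv(out / "annotations.csv")
    return out


def read_dataset(path) -> TemporalDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises a gap error listing the missing frames when the time axis is not
    contiguous, and a gap error when a manifest entry points to a missing
    file.  Non-watertight meshes produce a warning (they still load; only
    filled-mode rasterization skips them).
    """
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise ValidationError(f"{root}: no {MANIFEST_NAME} found")
    manifest = json.loads(manifest_path.read_text())
    n_times = int(manifest["n_times"])
    frames: list[list[LabeledObject]] = [[] for _ in range(n_times)]
    covered: set[int] = set()
    missing_files = []

    for entry in manifest.get("meshes", []):
        t, oid, name = int(entry["t"]), int(entry["id"]), entry["file"]
        f = root / name
        if not f.exists():
            missing_files.append(name)
            continue
        mesh = trimesh.load(f, file_type=f.suffix.lstrip("."), process=False)
        frames[t].append(LabeledObject(id=oid, mesh=mesh))
        covered.add(t)

    for entry in manifest.get("label_volumes", []):
        t, name = int(entry["t"]), entry["file"]
        f = root / name
        if not f.exists():
            missing_files.append(name)
            continue
        labels = np.asarray(tifffile.imread(f))
        if labels.ndim == 2:
            labels = labels[None, :, :]
        vol = LabelVolumeFrame(
            labels=labels.astype(np.int64),
            origin=np.asarray(entry["origin"], dtype=float),
            spacing=np.asarray(entry["spacing"], dtype=float),
        )
        for oid in sorted(vol.ids()):
            frames[t].append(LabeledObject(id=oid, voxels=vol))
        covered.add(t)

    if missing_files:
        raise ValidationError(f"{root}: manifest references missing files: {missing_files}")
    gaps = sorted(set(range(n_times)) - covered)
    if gaps:
        raise ValidationError(f"{root}: no objects for frames {gaps}")
    ds = TemporalDataset(frames)
    bad = ds.check_watertight()
    if bad:
        warnings.warn(f"non-watertight meshes for ids {bad}", stacklevel=2)
    return ds


def read_lineage(path) -> LineageTree:
    return LineageTree.from_csv(path)


def read_annotations(path) -> AnnotationTable:
    return AnnotationTable.from_csv(path)


# ---------------------------------------------------------------------------
# STC volume
# ---------------------------------------------------------------------------

def _manifest_path(volume_path: Path) -> Path:
    return volume_path.with_suffix(".json")


def write_stc(stc: STCVolume, path, normals=None) -> Path:
    """Write an STC as multi-page TIFF (page = time slice) or NRRD, plus a
    JSON manifest with the same stem.  Optionally caches the normal field
    as a float NRRD alongside (suffix ``.normals.nrrd``)."""
    path = Path(path)
    pages = np.moveaxis(stc.grid.astype(np.uint32), 2, 0)  # (T, n_v, n_u)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pages, photometric="minisblack")
    elif path.suffix.lower() == ".nrrd":
        write_nrrd(path, pages)
    else:
        raise ValidationError(f"unsupported STC extension {path.suffix!r} (use .tif/.tiff/.nrrd)")
    manifest = {
        "format": "sthcube-stc",
        "plane": {
            "point": stc.plane.point.tolist(),
            "normal": stc.plane.normal.tolist(),
            "up": stc.plane.up.tolist(),
        },
        "frame": stc.frame.to_dict(),
        "mode": stc.mode,
        "times": list(stc.times),
        "voxel_size": [stc.frame.pixel_size, stc.frame.pixel_size, 1.0],
        "axes": "page=k(time), row=v, col=u",
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if normals is not None:
        write_nrrd(path.with_suffix(".normals.nrrd"), normals.vectors.astype(np.float32))
    return path


def read_stc(path) -> STCVolume:
    """Read an STC volume and its manifest; raises a format error when the
    grid and manifest dimensions disagree."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = np.asarray(tifffile.imread(path))
    elif path.suffix.lower() == ".nrrd":
        pages = read_nrrd(path)
    else:
        raise ValidationError(f"unsupported STC extension {path.suffix!r}")
    if pages.ndim == 2:
        pages = pages[None, :, :]
    manifest = json.loads(_manifest_path(path).read_text())
    times = [int(t) for t in manifest["times"]]
    frame = CameraFrame.from_dict(manifest["frame"])
    if len(times) != pages.shape[0]:
        raise ValidationError(
            f"{path}: manifest lists {len(times)} times but volume has {pages.shape[0]} pages"
        )
    if (pages.shape[2], pages.shape[1]) != frame.resolution:
        raise ValidationError(f"{path}: page shape {pages.shape[1:]} does not match frame resolution")
    p = manifest["plane"]
    plane = PlaneSpec(
        point=np.asarray(p["point"], dtype=float),
        normal=np.asarray(p["normal"], dtype=float),
        up=np.asarray(p["up"], dtype=float),
    )
    grid = np.moveaxis(pages, 0, 2).astype(np.uint32)
    return STCVolume(grid=grid, plane=plane, frame=frame, mode=manifest["mode"], times=tuple(times))


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def read_params(path) -> SimulationParams:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if "asynchrony_set" in d:
        d["asynchrony_set"] = frozenset(int(i) for i in d["asynchrony_set"])
    if "deformation" in d and d["deformation"] is not None:
        amp, onset = d["deformation"]
        d["deformation"] = (float(amp), int(onset))
    return SimulationParams(**d)


def write_params(params: SimulationParams, path) -> None:
    d = {
        "n_initial_cells": params.n_initial_cells,
        "n_timesteps": params.n_timesteps,
        "division_period": params.division_period,
        "asynchrony_set": sorted(params.asynchrony_set),
        "jitter_sigma": params.jitter_sigma,
        "deformation": list(params.deformation) if params.deformation else None,
        "seed": params.seed,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_filters(path) -> FilterState:
    d = yaml.safe_load(Path(path).read_text()) or {}
    return FilterState(
        value_range=tuple(d["value_range"]) if d.get("value_range") else None,
        time_window=tuple(d["time_window"]) if d.get("time_window") else None,
        object_states={int(k): v for k, v in (d.get("object_states") or {}).items()},
        current_time=int(d.get("current_time", 0)),
    )


def write_filters(state: FilterState, path) -> None:
    d = {
        "value_range": list(state.value_range) if state.value_range else None,
        "time_window": list(state.time_window) if state.time_window else None,
        "object_states": {int(k): v for k, v in state.object_states.items()},
        "current_time": state.current_time,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_png(image: np.ndarray, path) -> None:
    """Write a float [0,1] RGB image as PNG (deterministic bytes)."""
    from PIL import Image

    arr = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path), format="PNG")
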