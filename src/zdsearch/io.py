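"""File formats and index persistence.

Descriptor tables are TSV: one row per structure, ``id`` followed by the
descriptor values (122 columns at order 20), optional header.  Voxel grids
are plain text rasters with a three-line header::

    Nx Ny Nz
    sx sy sz        (voxel spacing per axis)
    ox oy oz        (continuous coordinate of voxel (0, 0, 0))

followed by whitespace-separated values in x-fastest order.  Indexes persist
as a single ``.npz`` container: a JSON metadata entry (format version,
backend, parameters) plus flat arrays for the database and partition; an
index is rebuilt deterministically from the stored partition on load.
"""

from __future__ import annotations

import json
import math
import zipfile
from pathlib import Path

import numpy as np

from .exceptions import DescriptorParseError, IndexFormatError, ParameterError
from .extended import ReducedIndex, build_reduced
from .grid import VoxelGrid
from .idistance import IDistanceIndex, build_idistance
from .ikernel import IKernelIndex, build_ikernel
from .partitioning import DescriptorDatabase, Partition, _assemble

INDEX_FORMAT_VERSION = 1


# ---------------------------------------------------------------- descriptors

def read_descriptor_tsv(path) -> DescriptorDatabase:
    """Parse a descriptor TSV, validating values row by row.

    Rejects NaN and negative values, duplicate ids, and ragged rows with
    errors naming the offending (1-based) line.
    """
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    dim: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DescriptorParseError(f"{path}:{lineno}: expected id + values")
            if lineno == 1:
                try:
                    [float(v) for v in fields[1:]]
                except ValueError:
                    continue  # header line
            try:
                values = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise DescriptorParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if any(math.isnan(v) or math.isinf(v) for v in values):
                raise DescriptorParseError(f"{path}:{lineno}: non-finite value")
            if any(v < 0 for v in values):
                raise DescriptorParseError(f"{path}:{lineno}: negative invariant value")
            if dim is None:
                dim = len(values)
            elif len(values) != dim:
                raise DescriptorParseError(
                    f"{path}:{lineno}: expected {dim} values, found {len(values)}"
                )
            if fields[0] in seen:
                raise DescriptorParseError(f"{path}:{lineno}: duplicate id {fields[0]!r}")
            seen.add(fields[0])
            ids.append(fields[0])
            rows.append(values)
    if not rows:
        raise DescriptorParseError(f"{path}: no descriptor rows found")
    return DescriptorDatabase(ids=ids, X=np.asarray(rows))


def write_descriptor_tsv(db: DescriptorDatabase, path) -> Path:
    """Serialize with shortest round-trip decimals; byte output is stable."""
    path = Path(path)
    with path.open("w") as fh:
        for i, row in zip(db.ids, db.X):
            fh.write(i + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------- grids

def read_grid(path) -> VoxelGrid:
    path = Path(path)
    with path.open() as fh:
        try:
            shape = tuple(int(v) for v in fh.readline().split())
            spacing = np.array([float(v) for v in fh.readline().split()])
            origin = np.array([float(v) for v in fh.readline().split()])
            if len(shape) != 3 or spacing.size != 3 or origin.size != 3:
                raise ValueError("header must hold three triplets")
            values = np.loadtxt(fh).ravel().reshape(shape, order="F")
        except (ValueError, OSError) as exc:
            raise DescriptorParseError(f"{path}: malformed grid file ({exc})") from None
    return VoxelGrid(values=values, spacing=spacing, origin=origin)


def write_grid(grid: VoxelGrid, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(" ".join(str(s) for s in grid.shape) + "\n")
        fh.write(" ".join(repr(float(s)) for s in grid.spacing) + "\n")
        fh.write(" ".join(repr(float(s)) for s in grid.origin) + "\n")
        flat = grid.values.ravel(order="F")
        for start in range(0, flat.size, 8):
            fh.write(" ".join(repr(float(v)) for v in flat[start : start + 8]) + "\n")
    return path


# -------------------------------------------------------------------- indexes

def _partition_arrays(partition: Partition) -> dict[str, np.ndarray]:
    return {
        "centers": partition.centers,
        "labels": partition.labels,
    }


def save_index(index: IDistanceIndex | IKernelIndex | ReducedIndex, path) -> Path:
    """Persist an index as JSON metadata + flat arrays in one ``.npz``."""
    path = Path(path)
    if isinstance(index, IDistanceIndex):
        meta = {"kind": "idistance", "C": index.C}
        db, part = index.db, index.partition
    elif isinstance(index, IKernelIndex):
        meta = {"kind": "ikernel", "g": index.g}
        db, part = index.db, index.partition
    elif isinstance(index, ReducedIndex):
        meta = {
            "kind": "reduced",
            "backend": index.backend,
            "m": index.m,
            "multiplier": index.multiplier,
            "delta_r": index.delta_r,
        }
        if index.backend == "idistance":
            meta["C"] = index.inner.C  # type: ignore[union-attr]
        else:
            meta["g"] = index.inner.g  # type: ignore[union-attr]
        db, part = index.db, index.inner.partition
    else:
        raise ParameterError(f"cannot persist object of type {type(index).__name__}")
    meta["format_version"] = INDEX_FORMAT_VERSION
    meta["partition_method"] = part.method
    payload = {
        "meta": np.array(json.dumps(meta)),
        "ids": np.array(db.ids),
        "X": db.X,
        **_partition_arrays(part),
    }
    with path.open("wb") as fh:
        np.savez(fh, **payload)
    return path


def load_index(path) -> IDistanceIndex | IKernelIndex | ReducedIndex:
    """Rebuild an index from a persisted container.

    The partition (centers + method) is restored verbatim; the index
    structures are rebuilt from it, which is deterministic, so every query
    answer and evaluation count matches the saved index.
    """
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            ids = [str(s) for s in data["ids"]]
            X = np.asarray(data["X"], dtype=float)
            centers = np.asarray(data["centers"], dtype=float)
    except (OSError, zipfile.BadZipFile, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise IndexFormatError(f"{path}: not a readable index file ({exc})") from None
    version = meta.get("format_version")
    if version != INDEX_FORMAT_VERSION:
        raise IndexFormatError(
            f"{path}: index format version {version!r} not supported "
            f"(this build reads version {INDEX_FORMAT_VERSION})"
        )
    db = DescriptorDatabase(ids=ids, X=X)
    kind = meta.get("kind")
    if kind == "reduced":
        pdb = db.prefix(meta["m"])
        part = _assemble(pdb, centers, method=meta["partition_method"])
        return build_reduced(
            db,
            m=meta["m"],
            backend=meta["backend"],
            C=meta.get("C", 4.0),
            g=meta.get("g", 50),
            multiplier=meta["multiplier"],
            delta_r=meta.get("delta_r", 0.2),
            partition=part,
        )
    part = _assemble(db, centers, method=meta["partition_method"])
    if kind == "idistance":
        return build_idistance(db, part, C=meta["C"])
    if kind == "ikernel":
        return build_ikernel(db, part, g=meta["g"])
    raise IndexFormatError(f"{path}: unknown index kind {kind!r}")
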