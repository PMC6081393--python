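"""Mesh and landmark file I/O with validation.

Meshes are carried as :class:`trimesh.Trimesh` (millimetre units) throughout
the package; :func:`read_mesh` cleans on load (duplicate-vertex merge at
1e-6 mm, degenerate and duplicate faces dropped). Landmarks use the ten
anatomical point names of the neonatal maxilla (A, P, SA, SA', L, L', T, T',
SD, SD'), with primed names encoded by an ASCII ``p`` suffix; MT is always
derived as the T–T' midpoint and never stored.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import EmptyMeshError, LandmarkError, MeshFormatError

TriangleMesh = trimesh.Trimesh

#: Storable landmark names (MT is derived, never stored).
LANDMARK_NAMES = ("A", "P", "SA", "SAp", "L", "Lp", "T", "Tp", "SD", "SDp")

_UNIT_SCALE = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "um": 1e-3, "in": 25.4}

MERGE_TOL = 1e-6  # mm; below scanner resolution, above float noise


@dataclass
class MeshReport:
    """Validation summary of a triangle mesh."""

    is_manifold: bool
    is_watertight: bool
    n_boundary_loops: int
    n_components: int
    bbox: tuple[tuple[float, float, float], tuple[float, float, float]]
    volume: float | None  # mm^3, defined only when watertight
    surface_area: float  # mm^2

    def to_dict(self) -> dict:
        return {
            "is_manifold": self.is_manifold,
            "is_watertight": self.is_watertight,
            "n_boundary_loops": self.n_boundary_loops,
            "n_components": self.n_components,
            "bbox": [list(self.bbox[0]), list(self.bbox[1])],
            "volume": self.volume,
            "surface_area": self.surface_area,
        }


@dataclass
class LandmarkFileRecord:
    name: str
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.name not in LANDMARK_NAMES:
            raise LandmarkError(
                f"unknown landmark name {self.name!r}; allowed: {', '.join(LANDMARK_NAMES)}"
                + (" (MT is derived, never stored)" if self.name == "MT" else "")
            )
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise LandmarkError(f"landmark {self.name!r} needs 3 finite coordinates")


def _unit_factor(units: float | str | None) -> float:
    if units is None:
        return 1.0
    if isinstance(units, str):
        try:
            return _UNIT_SCALE[units]
        except KeyError:
            raise MeshFormatError(f"unknown unit hint {units!r}") from None
    return float(units)


def clean_mesh(mesh: trimesh.Trimesh, merge_tol: float = MERGE_TOL) -> trimesh.Trimesh:
    """Merge duplicate vertices within ``merge_tol`` and drop degenerate and
    duplicate faces. Returns a new mesh."""
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if len(verts) and merge_tol > 0:
        key = np.round(verts / merge_tol).astype(np.int64)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        verts = verts[first]
        faces = inverse[faces]
    # faces referencing the same vertex twice are degenerate
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    faces = faces[ok]
    # zero-area faces
    if len(faces):
        tri = verts[faces]
        area2 = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        faces = faces[area2 > 0]
    # duplicate faces (same vertex set, either winding)
    if len(faces):
        sorted_faces = np.sort(faces, axis=1)
        _, keep = np.unique(sorted_faces, axis=0, return_index=True)
        faces = faces[np.sort(keep)]
    out = trimesh.Trimesh(verts, faces, process=False)
    out.remove_unreferenced_vertices()
    return out


def _check_binary_stl(path: Path) -> None:
    """Raise MeshFormatError with a byte offset for truncated binary STL."""
    size = path.stat().st_size
    with open(path, "rb") as fh:
        head = fh.read(84)
    if len(head) < 84:
        raise MeshFormatError(f"binary STL {path} truncated in header", byte_offset=len(head))
    (n_tri,) = struct.unpack("<I", head[80:84])
    expected = 84 + 50 * n_tri
    if size < expected:
        raise MeshFormatError(
            f"binary STL {path} truncated: header promises {n_tri} facets "
            f"({expected} bytes), file has {size}",
            byte_offset=size,
        )


def _looks_binary_stl(path: Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(512)
    if len(head) < 84:
        return False
    if head.lstrip()[:5].lower() == b"solid":
        # ASCII unless the facet-count arithmetic works out exactly
        (n_tri,) = struct.unpack("<I", head[80:84])
        return path.stat().st_size == 84 + 50 * n_tri
    return True


def read_mesh(path, units: float | str | None = None) -> trimesh.Trimesh:
    """Read an STL (binary or ASCII) or OBJ file into a cleaned mm-unit mesh.

    ``units`` is a scale hint: a factor, or one of mm/cm/m/um/in.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "stl" and _looks_binary_stl(path):
        _check_binary_stl(path)
    try:
        mesh = trimesh.load_mesh(str(path), file_type=suffix or None, process=False)
    except EmptyMeshError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshFormatError(f"cannot read {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path} contains no geometry")
        mesh = trimesh.util.concatenate(geoms)
    if mesh.vertices.shape[0] == 0 or mesh.faces.shape[0] == 0:
        raise EmptyMeshError(f"{path} contains no triangles")
    out = clean_mesh(mesh)
    factor = _unit_factor(units)
    if factor != 1.0:
        out.apply_scale(factor)
    out.metadata["name"] = path.stem
    if out.faces.shape[0] == 0:
        raise EmptyMeshError(f"{path}: all faces degenerate after cleaning")
    return out


def write_mesh(mesh: trimesh.Trimesh, path, format: str | None = None) -> None:
    """Write a mesh as stl-binary, stl-ascii or obj (inferred from the path
    suffix when ``format`` is None; ``.stl`` defaults to binary)."""
    path = Path(path)
    if mesh.vertices.shape[0] == 0 or mesh.faces.shape[0] == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    if format is None:
        format = {"stl": "stl-binary", "obj": "obj"}.get(path.suffix.lower().lstrip("."), None)
        if format is None:
            raise MeshFormatError(f"cannot infer format from suffix of {path}")
    ftype = {"stl-binary": "stl", "stl-ascii": "stl_ascii", "obj": "obj"}.get(format)
    if ftype is None:
        raise MeshFormatError(f"unknown format {format!r}")
    try:
        data = trimesh.exchange.export.export_mesh(mesh, None, file_type=ftype)
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
    except OSError as exc:
        raise MeshFormatError(f"cannot write {path}: {exc}") from exc


def _boundary_loop_count(mesh: trimesh.Trimesh) -> int:
    """Number of closed loops formed by boundary edges (edges on 1 face)."""
    edges = mesh.edges_sorted
    if len(edges) == 0:
        return 0
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return 0
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(boundary.tolist())
    return sum(1 for _ in nx.connected_components(g))


def validate_mesh(mesh: trimesh.Trimesh) -> MeshReport:
    """Compute a :class:`MeshReport`; never raises, flags carry the verdict."""
    n_loops = _boundary_loop_count(mesh)
    # watertight = every edge on exactly 2 faces with consistent winding
    watertight = bool(mesh.is_watertight and mesh.is_winding_consistent)
    edges = mesh.edges_sorted
    if len(edges):
        _, counts = np.unique(edges, axis=0, return_counts=True)
        manifold = bool(np.all(counts <= 2))
    else:
        manifold = False
    volume = float(mesh.volume) if watertight else None
    return MeshReport(
        is_manifold=manifold,
        is_watertight=watertight,
        n_boundary_loops=n_loops,
        n_components=int(mesh.body_count),
        bbox=(tuple(mesh.bounds[0]), tuple(mesh.bounds[1])),
        volume=volume,
        surface_area=float(mesh.area),
    )


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


def _validate_records(records: list[LandmarkFileRecord]) -> list[LandmarkFileRecord]:
    seen = set()
    for rec in records:
        if rec.name in seen:
            raise LandmarkError(f"duplicate landmark name {rec.name!r}")
        seen.add(rec.name)
    return records


def read_landmarks(path) -> list[LandmarkFileRecord]:
    """Read landmarks from JSON (list of {name,x,y,z}) or CSV (name,x,y,z)."""
    path = Path(path)
    if not path.exists():
        raise LandmarkError(f"no such file: {path}")
    text = path.read_text()
    records: list[LandmarkFileRecord] = []
    if path.suffix.lower() == ".csv":
        reader = csv.DictReader(text.splitlines())
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["name", "x", "y", "z"]:
            raise LandmarkError(f"{path}: expected CSV header 'name,x,y,z'")
        for i, row in enumerate(reader):
            try:
                pos = [float(row["x"]), float(row["y"]), float(row["z"])]
            except (TypeError, ValueError) as exc:
                raise LandmarkError(f"{path} row {i + 2}: bad or missing coordinate") from exc
            records.append(LandmarkFileRecord(row["name"].strip(), pos))
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise LandmarkError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(data, list):
            raise LandmarkError(f"{path}: expected a JSON list of landmarks")
        for i, item in enumerate(data):
            try:
                pos = [float(item["x"]), float(item["y"]), float(item["z"])]
            except (KeyError, TypeError, ValueError) as exc:
                raise LandmarkError(f"{path} item {i}: bad or missing coordinate") from exc
            records.append(LandmarkFileRecord(str(item["name"]), pos))
    return _validate_records(records)


def write_landmarks(records: list[LandmarkFileRecord], path) -> None:
    """Write landmarks as JSON or CSV depending on the path suffix.

    Round trip is exact to 1e-9 mm (repr-precision floats)."""
    path = Path(path)
    _validate_records(records)
    if path.suffix.lower() == ".csv":
        lines = ["name,x,y,z"]
        for rec in records:
            x, y, z = (float(v) for v in rec.position)
            lines.append(f"{rec.name},{x!r},{y!r},{z!r}")
        path.write_text("\n".join(lines) + "\n")
    else:
        data = [
            {
                "name": rec.name,
                "x": float(rec.position[0]),
                "y": float(rec.position[1]),
                "z": float(rec.position[2]),
            }
            for rec in records
        ]
        path.write_text(json.dumps(data, indent=1))
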