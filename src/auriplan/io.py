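"""File I/O: STL/PLY/OBJ meshes, 3D Slicer FCSV landmarks, JSON landmarks/transforms.

Mesh parsing is delegated to :mod:`trimesh`; the only hand-written format
code is a double-precision ASCII PLY writer (the stock exporter emits
float32, which would break exact round-trips of mm-scale scan data).

The internal frame is RAS.  FCSV files declaring an LPS coordinate system
are converted on ingest by flipping x and y.
"""

from __future__ import annotations

import json
import os

import numpy as np
import trimesh as _trimesh

from .geometry import GeometryError, Isometry, LandmarkSet, TriMesh

__all__ = [
    "load_mesh",
    "save_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_isometry",
    "write_isometry",
    "MeshIOError",
]


class MeshIOError(IOError):
    """Unreadable, unwritable, or structurally empty mesh/landmark files."""


_EXT_FORMAT = {".stl": "stl", ".ply": "ply", ".obj": "obj"}


def _merge_exact_duplicates(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices equal bit-for-bit (no tolerance welding: deterministic)."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    # np.unique sorts; remap to first-appearance order for stability
    first = np.full(len(uniq), -1, dtype=np.int64)
    order = []
    for old, new in enumerate(inverse):
        if first[new] < 0:
            first[new] = len(order)
            order.append(old)
    remap = first[inverse]
    return vertices[np.array(order)], remap[faces]


def load_mesh(path: str, format: str = "auto") -> TriMesh:
    """Load a surface mesh (STL binary/ASCII, PLY, OBJ) into a :class:`TriMesh`.

    STL files carry an unindexed triangle soup; coincident vertices are
    merged by exact coordinate equality.  Indexed formats (PLY, OBJ) keep
    the file's vertex array as-is.  Face winding is preserved from the file.
    """
    if not os.path.exists(path):
        raise MeshIOError(f"mesh file not found: {path}")
    fmt = format
    if fmt == "auto":
        fmt = _EXT_FORMAT.get(os.path.splitext(path)[1].lower())
        if fmt is None:
            raise MeshIOError(f"cannot infer mesh format from {path!r}")
    try:
        raw = _trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise MeshIOError(f"failed to parse {path}: {exc}") from exc
    v = np.asarray(raw.vertices, dtype=float)
    f = np.asarray(raw.faces, dtype=np.int64)
    if len(f) == 0:
        raise MeshIOError(f"mesh has zero faces: {path}")
    if fmt == "stl":
        v, f = _merge_exact_duplicates(v, f)
    return TriMesh(v, f, name=os.path.splitext(os.path.basename(path))[0])


def _write_ply_double(mesh: TriMesh, path: str, scalar=None, scalar_name: str = "quality") -> None:
    # ASCII PLY with double properties; %.17g round-trips IEEE float64.
    extra = f"property double {scalar_name}\n" if scalar is not None else ""
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(mesh.vertices)}\n"
            "property double x\nproperty double y\nproperty double z\n"
            f"{extra}"
            f"element face {len(mesh.faces)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        if scalar is None:
            for p in mesh.vertices:
                fh.write("%.17g %.17g %.17g\n" % (p[0], p[1], p[2]))
        else:
            for p, s in zip(mesh.vertices, scalar):
                fh.write("%.17g %.17g %.17g %.17g\n" % (p[0], p[1], p[2], s))
        for f in mesh.faces:
            fh.write("3 %d %d %d\n" % (f[0], f[1], f[2]))


def save_distance_map_ply(mesh: TriMesh, values, path: str) -> None:
    """Write a mesh with one per-vertex signed-distance scalar as ASCII PLY."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(mesh.vertices):
        raise MeshIOError("per-vertex value count does not match the mesh")
    _write_ply_double(mesh, path, scalar=values, scalar_name="signed_distance")


def save_mesh(mesh: TriMesh, path: str, format: str = "auto") -> None:
    """Write a mesh as ``stl_binary``, ``stl_ascii``, ``ply`` (float64) or ``obj``."""
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        format = {".stl": "stl_binary", ".ply": "ply", ".obj": "obj"}.get(ext)
        if format is None:
            raise MeshIOError(f"cannot infer mesh format from {path!r}")
    try:
        if format == "ply":
            _write_ply_double(mesh, path)
            return
        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        if format == "stl_binary":
            data = tm.export(file_type="stl")
        elif format == "stl_ascii":
            data = tm.export(file_type="stl_ascii").encode()
        elif format == "obj":
            data = tm.export(file_type="obj").encode()
        else:
            raise MeshIOError(f"unknown mesh format {format!r}")
        with open(path, "wb") as fh:
            fh.write(data)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str, dialect: str = "auto") -> LandmarkSet:
    """Read landmarks from a Slicer markups FCSV file or the package JSON dialect.

    FCSV rows are ``id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,...``; a
    ``# CoordinateSystem = LPS`` (or ``= 0``) header triggers conversion to
    RAS by negating x and y.
    """
    if dialect == "auto":
        dialect = "json" if path.lower().endswith(".json") else "fcsv"
    if dialect == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return LandmarkSet(
            {k: np.asarray(v, dtype=float) for k, v in doc["landmarks"].items()},
            frame=doc.get("frame", "RAS"),
        )
    if dialect != "fcsv":
        raise MeshIOError(f"unknown landmark dialect {dialect!r}")

    lps = False
    entries: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("# ").replace(" ", "")
                if header.lower().startswith("coordinatesystem="):
                    value = header.split("=", 1)[1]
                    lps = value.upper() == "LPS" or value == "0"
                continue
            cols = line.split(",")
            if len(cols) < 12:
                raise MeshIOError(f"{path}:{lineno}: expected >= 12 columns, got {len(cols)}")
            try:
                xyz = np.array([float(cols[1]), float(cols[2]), float(cols[3])])
            except ValueError as exc:
                raise MeshIOError(f"{path}:{lineno}: non-numeric coordinate") from exc
            label = cols[11].strip()
            if not label:
                label = cols[0].strip()
            if label in entries:
                raise MeshIOError(f"{path}:{lineno}: duplicate label {label!r}")
            if lps:
                xyz = xyz * np.array([-1.0, -1.0, 1.0])
            entries[label] = xyz
    return LandmarkSet(entries, frame="RAS")


def write_landmarks(landmarks: LandmarkSet, path: str, dialect: str = "auto") -> None:
    if dialect == "auto":
        dialect = "json" if path.lower().endswith(".json") else "fcsv"
    if dialect == "json":
        doc = {
            "frame": landmarks.frame,
            "landmarks": {k: [float(c) for c in v] for k, v in landmarks.entries.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
        return
    with open(path, "w") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        for i, (name, p) in enumerate(landmarks.entries.items(), start=1):
            fh.write(
                f"F-{i},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g},0,0,0,1,1,1,0,{name},,\n"
            )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def read_isometry(path: str) -> Isometry:
    """Read a transform stored as row-major 16 floats plus a ``kind`` flag."""
    with open(path) as fh:
        doc = json.load(fh)
    m = np.asarray(doc["matrix"], dtype=float).reshape(4, 4)
    return Isometry(m, doc.get("kind", "rigid"))


def write_isometry(t: Isometry, path: str) -> None:
    doc = {"matrix": [float(x) for x in t.matrix.ravel()], "kind": t.kind}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
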