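"""Core geometric types: triangle meshes, rigid/reflective isometries, planes, landmarks.

All coordinates are millimetres in a right-handed RAS frame
(x = patient right, y = anterior, z = superior) unless a loader is told
otherwise.  Transforms are 4x4 homogeneous matrices acting on column
points; ``compose(A, B)`` applies ``B`` first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TriMesh",
    "Isometry",
    "Plane",
    "LandmarkSet",
    "reflect_across_plane",
    "GeometryError",
]

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Raised when a geometric object violates its invariants."""


@dataclass(frozen=True)
class Isometry:
    """A rigid (det +1) or reflective (det -1) isometry of 3-space.

    Parameters
    ----------
    matrix : (4, 4) array
        Homogeneous transform acting on column vectors.
    kind : {"rigid", "reflective"}
        Must agree with the determinant of the linear block.
    """

    matrix: np.ndarray
    kind: str = "rigid"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError(f"matrix must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise GeometryError("matrix contains non-finite entries")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise GeometryError("bottom row must be (0,0,0,1)")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError("linear block is not orthogonal within 1e-9")
        det = np.linalg.det(r)
        expected = {"rigid": 1.0, "reflective": -1.0}
        if self.kind not in expected:
            raise GeometryError(f"kind must be rigid or reflective, got {self.kind!r}")
        if abs(det - expected[self.kind]) > 1e-6:
            raise GeometryError(f"det(R)={det:.6f} inconsistent with kind={self.kind!r}")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "Isometry":
        return Isometry(np.eye(4), "rigid")

    @staticmethod
    def from_rotation_translation(rotation: np.ndarray, translation: np.ndarray) -> "Isometry":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        kind = "rigid" if np.linalg.det(rotation) > 0 else "reflective"
        return Isometry(m, kind)

    # -- algebra -----------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def compose(self, other: "Isometry") -> "Isometry":
        """Return self ∘ other (``other`` is applied first)."""
        kind = "rigid" if self.kind == other.kind else "reflective"
        return Isometry(self.matrix @ other.matrix, kind)

    def invert(self) -> "Isometry":
        r = self.rotation.T
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = -r @ self.translation
        return Isometry(m, self.kind)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points (or a single point)."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out


@dataclass(frozen=True)
class Plane:
    """Oriented plane {x : normal·x = offset}; normal is unit length, offset in mm."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-6:
            if norm == 0 or not np.isfinite(norm):
                raise GeometryError("plane normal must be a nonzero finite vector")
            n = n / norm
        # renormalise to meet the 1e-12 unit-norm invariant
        n = n / np.linalg.norm(n)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = p @ self.normal - self.offset
        return d[0] if np.asarray(points).ndim == 1 else d

    def transformed(self, t: Isometry) -> "Plane":
        """The image of this plane under the isometry ``t``."""
        n = t.rotation @ self.normal
        # point on plane: offset * normal maps to t.apply(...)
        p = t.apply(self.offset * self.normal)
        return Plane(n, float(n @ p))


def reflect_across_plane(plane: Plane) -> Isometry:
    """Householder reflection across a plane: linear part I − 2nnᵀ, translation 2dn."""
    n = plane.normal
    m = np.eye(4)
    m[:3, :3] = np.eye(3) - 2.0 * np.outer(n, n)
    m[:3, 3] = 2.0 * plane.offset * n
    return Isometry(m, "reflective")


@dataclass
class TriMesh:
    """An indexed triangle surface in mm with counter-clockwise (outward) winding.

    Degenerate (zero-area) faces are retained but flagged via
    :attr:`degenerate_faces`; distance queries skip them.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise GeometryError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise GeometryError(f"faces must be (m, 3), got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise GeometryError("vertex coordinates must be finite")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise GeometryError("face indices out of range")
        if f.size and (
            np.any(f[:, 0] == f[:, 1]) or np.any(f[:, 1] == f[:, 2]) or np.any(f[:, 0] == f[:, 2])
        ):
            raise GeometryError("a face references the same vertex twice")
        self.vertices = v
        self.faces = f

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    @property
    def face_normals(self) -> np.ndarray:
        """Unit outward normals; zero vector for degenerate faces."""
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        lg = np.linalg.norm(n, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(lg[:, None] > 0, n / np.where(lg[:, None] == 0, 1, lg[:, None]), 0.0)
        return out

    @property
    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    @property
    def degenerate_faces(self) -> np.ndarray:
        """Boolean mask of zero-area faces (kept in the mesh, skipped by queries)."""
        return self.face_areas <= 0.0

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for a closed, outward-wound mesh."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def area(self) -> float:
        return float(self.face_areas.sum())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def apply_isometry(mesh: TriMesh, t: Isometry) -> TriMesh:
    """Transform a mesh, flipping winding under reflections so normals stay outward."""
    v = t.apply(mesh.vertices)
    f = mesh.faces[:, ::-1].copy() if t.kind == "reflective" else mesh.faces.copy()
    return TriMesh(v, f, mesh.name)


@dataclass
class LandmarkSet:
    """Named anatomical 3D points (mm) in a labelled coordinate frame."""

    entries: dict
    frame: str = "RAS"

    def __post_init__(self):
        clean = {}
        for name, p in self.entries.items():
            pt = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(pt)):
                raise GeometryError(f"landmark {name!r} has non-finite coordinates")
            if name in clean:
                raise GeometryError(f"duplicate landmark name {name!r}")
            clean[str(name)] = pt
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self):
        return list(self.entries)

    def points(self) -> np.ndarray:
        return np.array([self.entries[k] for k in self.entries])

    def transformed(self, t: Isometry) -> "LandmarkSet":
        return LandmarkSet({k: t.apply(v) for k, v in self.entries.items()}, self.frame)
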