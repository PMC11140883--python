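"""Midsagittal plane estimation and specular (mirrored) ear planning.

The surgical target for a unilateral microtia reconstruction is the mirror
image of the healthy ear across the head's midsagittal plane.  The plane
itself is estimated by mirror-ICP: reflect a vertex subsample across a
candidate plane, rigidly register the reflection back onto the head, and
read the symmetry plane off the composed reflective transform; iterate.
Trimmed correspondences make the estimate robust to the asymmetric
(microtic or absent) ear.
"""

from __future__ import annotations

import numpy as np

from .geometry import (
    GeometryError,
    Isometry,
    LandmarkSet,
    Plane,
    TriMesh,
    reflect_across_plane,
)
from .registration import IcpParams, RegistrationError, icp

__all__ = [
    "estimate_sagittal_plane",
    "crop_region",
    "make_specular_ear",
    "mirror_residual",
    "SymmetryError",
]

MIDLINE_NAMES = ("nasion", "subnasale", "nose", "forehead", "chin", "glabella")
_PAIR_NAMES = (("eye_l", "eye_r"), ("ear_l", "ear_r"), ("canthus_l", "canthus_r"))

MAX_OUTER_ITER = 50
NORMAL_TOL_DEG = 0.01
OFFSET_TOL_MM = 0.01
SUBSAMPLE = 5000


class SymmetryError(RuntimeError):
    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


def _plane_from_reflective(t: Isometry) -> Plane:
    """Fixed plane of a (near-)reflection A x + b: normal from the -1
    eigendirection of the symmetrised linear part, offset = n·b / 2."""
    a = t.rotation
    s = 0.5 * (np.eye(3) - 0.5 * (a + a.T))
    evals, evecs = np.linalg.eigh(s)
    n = evecs[:, np.argmax(evals)]
    d = 0.5 * float(n @ t.translation)
    if d < 0:
        n, d = -n, -d
    return Plane(n, d)


def _initial_plane(head: TriMesh, landmarks: LandmarkSet | None) -> Plane:
    if landmarks is not None:
        for left, right in _PAIR_NAMES:
            if left in landmarks and right in landmarks:
                a, b = landmarks[left], landmarks[right]
                n = b - a
                norm = np.linalg.norm(n)
                if norm > 1e-9:
                    n = n / norm
                    mid = 0.5 * (a + b)
                    return Plane(n, float(n @ mid))
        mids = [landmarks[m] for m in MIDLINE_NAMES if m in landmarks]
        if len(mids) >= 2:
            # plane containing the midline points, normal orthogonal to their
            # span and to the head's long (superior-inferior) axis
            mids = np.asarray(mids)
            span = mids[-1] - mids[0]
            span /= np.linalg.norm(span)
            cov = np.cov(head.vertices.T)
            axis = np.linalg.eigh(cov)[1][:, -1]
            n = np.cross(span, axis)
            if np.linalg.norm(n) > 1e-6:
                n /= np.linalg.norm(n)
                return Plane(n, float(n @ mids.mean(axis=0)))
    # fall back on the least-variance principal axis through the centroid
    cov = np.cov(head.vertices.T)
    n = np.linalg.eigh(cov)[1][:, 0]
    c = head.centroid()
    return Plane(n, float(n @ c))


def mirror_residual(head: TriMesh, plane: Plane, sample: np.ndarray) -> float:
    """RMS point-to-surface distance of reflected sample points to the head."""
    from .proximity import SurfaceQuery

    refl = reflect_across_plane(plane)
    _, d, _ = SurfaceQuery(head).query(refl.apply(sample))
    return float(np.sqrt(np.mean(d**2)))


def estimate_sagittal_plane(
    head: TriMesh,
    landmarks: LandmarkSet | None = None,
    seed: int = 0,
    subsample: int = SUBSAMPLE,
    max_iter: int = MAX_OUTER_ITER,
) -> Plane:
    """Estimate the midsagittal plane of a head mesh by mirror-ICP.

    Initialised from landmarks (perpendicular bisector of a left/right pair,
    or a plane through midline points) or, failing that, from the
    least-variance principal axis.  Raises :class:`SymmetryError` carrying
    the last mirror residual if the refinement does not converge.
    """
    if len(head.vertices) < 100:
        raise GeometryError("head mesh needs at least 100 vertices")
    plane = _initial_plane(head, landmarks)
    rng = np.random.default_rng(seed)
    n = len(head.vertices)
    k = min(subsample, n)
    idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
    sample = head.vertices[idx]
    params = IcpParams(max_iter=15, tol_mm=1e-4, reject_percentile=80.0)

    last_residual = None
    for _ in range(max_iter):
        refl = reflect_across_plane(plane)
        try:
            result = icp(refl.apply(sample), head, params=params)
        except RegistrationError as exc:
            raise SymmetryError(f"mirror-ICP failed: {exc}", residual=last_residual)
        last_residual = result.rms
        composed = result.transform.compose(refl)
        new_plane = _plane_from_reflective(composed)
        # keep orientation stable across iterations
        if float(new_plane.normal @ plane.normal) < 0:
            new_plane = Plane(-new_plane.normal, -new_plane.offset)
        dot = np.clip(abs(float(new_plane.normal @ plane.normal)), -1.0, 1.0)
        dang = np.degrees(np.arccos(dot))
        doff = abs(new_plane.offset - plane.offset)
        plane = new_plane
        if dang < NORMAL_TOL_DEG and doff < OFFSET_TOL_MM:
            return plane
    raise SymmetryError(
        f"sagittal-plane refinement did not converge in {max_iter} iterations",
        residual=last_residual,
    )


def crop_region(mesh: TriMesh, center, radius: float) -> TriMesh:
    """Submesh of faces whose three corners all lie within ``radius`` of ``center``."""
    if radius <= 0:
        raise GeometryError("crop radius must be positive")
    c = np.asarray(center, dtype=float).reshape(3)
    inside = np.linalg.norm(mesh.vertices - c, axis=1) <= radius
    keep = inside[mesh.faces].all(axis=1)
    if not keep.any():
        raise SymmetryError("crop region contains no faces")
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(mesh.vertices[used].copy(), remap[faces], name=f"{mesh.name}_crop")


def make_specular_ear(healthy_ear: TriMesh, plane: Plane) -> TriMesh:
    """Reflect the healthy ear across the sagittal plane: the plan-frame target ear."""
    from .geometry import apply_isometry

    out = apply_isometry(healthy_ear, reflect_across_plane(plane))
    out.name = f"{healthy_ear.name}_specular" if healthy_ear.name else "specular_ear"
    return out
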