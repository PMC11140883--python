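"""Rigid surface registration.

Two layers: a closed-form weighted least-squares solve from known point
correspondences (Kabsch/Umeyama without scaling; reflections excluded by
construction), and trimmed point-to-surface ICP with optional
landmark-sphere masking of the source — the "align on the most similar
surfaces" step used when a postoperative scan is compared to the plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, Isometry, LandmarkSet, TriMesh
from .proximity import SurfaceQuery

__all__ = [
    "RegistrationResult",
    "RegistrationError",
    "rigid_from_correspondences",
    "icp",
    "mask_from_landmarks",
    "IcpParams",
]

DEFAULT_MASK_RADIUS_MM = 25.0


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationResult:
    transform: Isometry
    rms: float
    iterations: int
    converged: bool
    correspondences_used: list = field(default_factory=list)
    rms_history: list = field(default_factory=list)

    def __post_init__(self):
        if self.rms < 0:
            raise GeometryError("rms must be non-negative")
        if self.iterations < 1:
            raise GeometryError("iterations must be >= 1")


def rigid_from_correspondences(source, target, weights=None) -> RegistrationResult:
    """Optimal rigid transform mapping ``source`` points onto ``target`` points.

    Weighted Kabsch: the SVD of the weighted cross-covariance gives the
    rotation; if the raw solution would be a reflection the smallest
    singular direction is negated.  ``rms`` is the weighted RMS residual
    after the fit.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise GeometryError("source/target must be matching (n, 3) arrays")
    n = len(s)
    if n < 3:
        raise RegistrationError("need at least 3 correspondences")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise GeometryError("weights must be non-negative with positive sum")
    w = w / w.sum()

    sc = (w[:, None] * s).sum(axis=0)
    tc = (w[:, None] * t).sum(axis=0)
    s0 = s - sc
    t0 = t - tc
    h = (w[:, None] * s0).T @ t0
    u, sig, vt = np.linalg.svd(h)
    # collinear or coincident configurations leave the in-plane rotation free
    scale = max(sig[0], 1e-30)
    if sig[1] / scale < 1e-9 and not np.allclose(t0, 0.0, atol=1e-12):
        raise RegistrationError("degenerate (collinear) correspondence geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - r @ sc
    transform = Isometry.from_rotation_translation(r, trans)
    resid = (s @ r.T + trans) - t
    rms = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum()))
    return RegistrationResult(transform, rms, iterations=1, converged=True,
                              correspondences_used=[n])


def mask_from_landmarks(
    mesh: TriMesh,
    landmarks: LandmarkSet,
    names,
    radius: float = DEFAULT_MASK_RADIUS_MM,
) -> np.ndarray:
    """Vertex indices within ``radius`` of any named landmark (union of spheres)."""
    missing = [n for n in names if n not in landmarks]
    if missing:
        raise KeyError(f"landmarks not found: {missing}")
    keep = np.zeros(len(mesh.vertices), dtype=bool)
    for n in names:
        keep |= np.linalg.norm(mesh.vertices - landmarks[n], axis=1) <= radius
    return np.flatnonzero(keep)


@dataclass
class IcpParams:
    """Knobs of the trimmed point-to-surface ICP.

    reject_percentile drops the worst residuals each iteration (90 keeps
    the best 90%); tol_mm stops when the rms improves by less than this.
    """

    max_iter: int = 100
    tol_mm: float = 1e-4
    reject_percentile: float = 90.0


def _rodrigues(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    if theta < 1e-14:
        return np.eye(3)
    k = w / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx


def icp(
    source,
    target: TriMesh,
    init: Isometry | None = None,
    mask=None,
    params: IcpParams | None = None,
) -> RegistrationResult:
    """Trimmed point-to-surface ICP of source vertices onto a target mesh.

    ``source`` is a TriMesh or an (n, 3) point array; ``mask`` (optional)
    is an index array into the source vertices.  Correspondences are exact
    foot points on target triangles; each iteration takes a linearised
    point-to-plane Gauss-Newton step (point-to-point steps slide
    tangentially on smooth anatomy and stall far from the optimum).  The
    point-to-surface rms is enforced non-increasing across accepted
    iterations: a step that raises it is rolled back and the loop stops.
    """
    params = params or IcpParams()
    pts = source.vertices if isinstance(source, TriMesh) else np.asarray(source, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=np.int64)
        if mask.size == 0:
            raise RegistrationError("empty source mask")
        pts = pts[mask]
    if len(pts) < 3:
        raise RegistrationError("need at least 3 source points")

    query = SurfaceQuery(target)
    normals = target.face_normals
    current = init if init is not None else Isometry.identity()
    prev_rms = None
    prev_transform = current
    used = []
    history = []
    converged = False

    for _ in range(params.max_iter):
        moved = current.apply(pts)
        feet, dist, fidx = query.query(moved)
        if not np.all(np.isfinite(dist)):
            raise RegistrationError("non-finite residuals in closest-point query")
        rms = float(np.sqrt(np.mean(dist**2)))
        if prev_rms is not None and rms > prev_rms + 1e-12:
            current = prev_transform  # roll back the worsening step
            converged = True
            break
        if params.reject_percentile < 100:
            keep = dist <= np.percentile(dist, params.reject_percentile)
            if keep.sum() < 3:
                keep = np.ones(len(dist), dtype=bool)
        else:
            keep = np.ones(len(dist), dtype=bool)
        used.append(int(keep.sum()))
        history.append(rms)
        if prev_rms is not None and prev_rms - rms < params.tol_mm:
            converged = True
            break
        prev_rms, prev_transform = rms, current
        # point-to-plane step: minimise sum(((p + w x p + t - f) . n)^2)
        p, f = moved[keep], feet[keep]
        n = normals[fidx[keep]]
        b = -np.einsum("ij,ij->i", p - f, n)
        a = np.hstack([np.cross(p, n), n])
        x, *_ = np.linalg.lstsq(a, b, rcond=None)
        step = Isometry.from_rotation_translation(_rodrigues(x[:3]), x[3:])
        current = step.compose(current)
    else:
        current = prev_transform  # rms reported matches the returned transform

    if not history or not np.isfinite(history[-1]):
        raise RegistrationError("ICP produced non-finite rms")
    return RegistrationResult(
        current, history[-1], len(history), converged, used, history
    )
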