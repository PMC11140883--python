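"""Geometry under the intraoperative AR overlay.

A patterned cube is rigidly linked to the patient through a dental splint;
detecting the cube in the tablet camera anchors the planned (specular) ear
in the camera frame through the chain

    T_cam<-earplan = T_cam<-marker · T_marker<-splint · T_splint<-head · T_head<-earplan

Pattern detection itself is out of scope: the interface is per-corner
pixel observations.  The pose solve is a planar-homography initialisation
refined by damped (Levenberg) Gauss-Newton on the reprojection error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, Isometry
from .registration import RegistrationResult

__all__ = [
    "CameraModel",
    "MarkerModel",
    "GuidanceChain",
    "project_points",
    "estimate_marker_pose",
    "compose_guidance",
    "silhouette_overlay_error",
    "tracking_status",
    "ProjectionError",
    "PoseError",
    "TRACKING_THRESHOLD_PX",
]

TRACKING_THRESHOLD_PX = 2.0
DEFAULT_CUBE_SIDE_MM = 30.0


class ProjectionError(ValueError):
    pass


class PoseError(RuntimeError):
    def __init__(self, msg, rms=None):
        super().__init__(msg)
        self.rms = rms


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with optional two-term radial distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    image_size: tuple = (1920, 1080)
    distortion: tuple | None = None  # (k1, k2)

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise GeometryError("focal lengths must be positive")
        w, h = self.image_size
        if not (0 <= self.cx <= w and 0 <= self.cy <= h):
            raise GeometryError("principal point must lie inside the image")

    @staticmethod
    def from_dict(doc: dict) -> "CameraModel":
        dist = doc.get("distortion")
        return CameraModel(
            fx=doc["fx"], fy=doc["fy"], cx=doc["cx"], cy=doc["cy"],
            image_size=tuple(doc.get("image_size", (1920, 1080))),
            distortion=tuple(dist) if dist else None,
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "image_size": list(self.image_size),
            "distortion": list(self.distortion) if self.distortion else None,
        }


# face order: +x, -x, +y, -y, +z, -z ; per-face in-plane axes (u, v) satisfy
# u x v = outward normal, corners CCW from outside starting at +u+v.
_FACE_AXES = {
    0: ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    1: ((-1, 0, 0), (0, 0, 1), (0, 1, 0)),
    2: ((0, 1, 0), (0, 0, 1), (1, 0, 0)),
    3: ((0, -1, 0), (1, 0, 0), (0, 0, 1)),
    4: ((0, 0, 1), (1, 0, 0), (0, 1, 0)),
    5: ((0, 0, -1), (0, 1, 0), (1, 0, 0)),
}


@dataclass(frozen=True)
class MarkerModel:
    """Cube fiducial: per-face squares of 4 corners in the marker frame (mm)."""

    side: float
    faces: dict = field(default_factory=dict)  # face id -> (4, 3) corners

    def __post_init__(self):
        if self.side <= 0:
            raise GeometryError("cube side must be positive")
        for fid, corners in self.faces.items():
            c = np.asarray(corners, dtype=float)
            if c.shape != (4, 3):
                raise GeometryError(f"face {fid}: need 4 corner points")
            # coplanar square of the stated side
            edges = np.roll(c, -1, axis=0) - c
            if not np.allclose(np.linalg.norm(edges, axis=1), self.side, atol=1e-9):
                raise GeometryError(f"face {fid}: corners do not form a square of side {self.side}")
            n = np.cross(edges[0], edges[1])
            if abs(np.dot(c[2] - c[0], n) / np.linalg.norm(n)) > 1e-9:
                raise GeometryError(f"face {fid}: corners not coplanar")
            object.__setattr__(self, "faces", {**self.faces, fid: c})

    @staticmethod
    def cube(side: float = DEFAULT_CUBE_SIDE_MM) -> "MarkerModel":
        faces = {}
        h = side / 2.0
        for fid, (n, u, v) in _FACE_AXES.items():
            n, u, v = (np.asarray(a, dtype=float) for a in (n, u, v))
            center = n * h
            faces[fid] = np.array(
                [center + h * (su * u + sv * v) for su, sv in ((1, 1), (-1, 1), (-1, -1), (1, -1))]
            )
        return MarkerModel(side, faces)

    def face_normal(self, fid: int) -> np.ndarray:
        c = self.faces[fid]
        n = np.cross(c[1] - c[0], c[3] - c[0])
        return n / np.linalg.norm(n)

    def corner(self, fid: int, idx: int) -> np.ndarray:
        return self.faces[fid][idx]


@dataclass(frozen=True)
class GuidanceChain:
    """The three rigid links anchoring the planned ear to the tracked marker."""

    T_marker_from_splint: Isometry
    T_splint_from_head: Isometry
    T_head_from_earplan: Isometry = field(default_factory=Isometry.identity)

    def __post_init__(self):
        for t in (self.T_marker_from_splint, self.T_splint_from_head, self.T_head_from_earplan):
            if t.kind != "rigid":
                raise GeometryError("guidance chain links must be rigid")


def project_points(camera: CameraModel, T_cam_from_obj: Isometry, points) -> np.ndarray:
    """Pinhole projection of object-frame points to pixel coordinates."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    cam_pts = T_cam_from_obj.apply(p)
    z = cam_pts[:, 2]
    bad = np.flatnonzero(z <= 1e-9)
    if bad.size:
        raise ProjectionError(f"points at or behind the camera plane: indices {bad.tolist()}")
    xn = cam_pts[:, 0] / z
    yn = cam_pts[:, 1] / z
    if camera.distortion is not None:
        k1, k2 = camera.distortion
        r2 = xn**2 + yn**2
        factor = 1.0 + k1 * r2 + k2 * r2**2
        xn = xn * factor
        yn = yn * factor
    return np.column_stack([camera.fx * xn + camera.cx, camera.fy * yn + camera.cy])


def _normalized(camera: CameraModel, pixels: np.ndarray) -> np.ndarray:
    """Pixels -> normalized image coordinates, undoing radial distortion."""
    xn = (pixels[:, 0] - camera.cx) / camera.fx
    yn = (pixels[:, 1] - camera.cy) / camera.fy
    if camera.distortion is not None:
        k1, k2 = camera.distortion
        xd, yd = xn.copy(), yn.copy()
        for _ in range(20):  # fixed-point undistortion
            r2 = xn**2 + yn**2
            factor = 1.0 + k1 * r2 + k2 * r2**2
            xn, yn = xd / factor, yd / factor
    return np.column_stack([xn, yn])


def _homography_pose(marker, camera, obs_by_face) -> Isometry:
    fid = max(obs_by_face, key=lambda f: len(obs_by_face[f]))
    obs = obs_by_face[fid]
    if len(obs) < 4:
        raise PoseError("homography initialisation needs a face with 4 observed corners")
    corners3d = np.array([marker.corner(fid, ci) for ci, _ in obs])
    pix = np.array([uv for _, uv in obs])
    # face-local 2D frame
    origin = corners3d.mean(axis=0)
    n = marker.face_normal(fid)
    u = corners3d[0] - origin
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    ab = np.column_stack([(corners3d - origin) @ u, (corners3d - origin) @ v])
    xy = _normalized(camera, pix)
    # DLT for the 3x3 homography [a b 1] -> lambda [x y 1]
    rows = []
    for (a, b), (x, y) in zip(ab, xy):
        rows.append([-a, -b, -1, 0, 0, 0, x * a, x * b, x])
        rows.append([0, 0, 0, -a, -b, -1, y * a, y * b, y])
    _, _, vt = np.linalg.svd(np.asarray(rows))
    h = vt[-1].reshape(3, 3)
    h1, h2, h3 = h[:, 0], h[:, 1], h[:, 2]
    s = 0.5 * (np.linalg.norm(h1) + np.linalg.norm(h2))
    if s < 1e-15:
        raise PoseError("degenerate homography")
    r1, r2, t = h1 / s, h2 / s, h3 / s
    if t[2] < 0:  # marker must be in front of the camera
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    uu, _, vv = np.linalg.svd(np.column_stack([r1, r2, r3]))
    r = uu @ vv
    if np.linalg.det(r) < 0:
        uu[:, -1] *= -1
        r = uu @ vv
    T_cam_from_face = Isometry.from_rotation_translation(r, t)
    m = np.column_stack([u, v, n])
    T_face_from_marker = Isometry.from_rotation_translation(m.T, -m.T @ origin)
    return T_cam_from_face.compose(T_face_from_marker)


def _rodrigues(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    if theta < 1e-14:
        return np.eye(3)
    k = w / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx


def estimate_marker_pose(
    observations,
    marker: MarkerModel,
    camera: CameraModel,
    init: Isometry | None = None,
    max_iter: int = 100,
) -> RegistrationResult:
    """Solve the camera-from-marker pose from corner observations.

    ``observations`` is a sequence of ``(face_id, corner_index, (u, v))``.
    Initialised from a planar homography on the most-observed face when no
    ``init`` is given, then refined by Gauss-Newton with Levenberg damping
    (lambda starts at 1e-3, x10 on a rejected step, /10 on an accepted one).
    The reported rms is the per-corner RMS reprojection distance in pixels.
    """
    obs = list(observations)
    if len(obs) < 4:
        raise PoseError(f"need at least 4 corner observations, got {len(obs)}")
    pts3d = np.array([marker.corner(f, c) for f, c, _ in obs])
    pix = np.array([uv for _, _, uv in obs], dtype=float)
    if np.linalg.matrix_rank(pts3d - pts3d.mean(axis=0), tol=1e-9) < 2:
        raise PoseError("observed corners are collinear")

    if init is None:
        by_face: dict = {}
        for f, c, uv in obs:
            by_face.setdefault(f, []).append((c, uv))
        pose = _homography_pose(marker, camera, by_face)
    else:
        pose = init

    def residual(p: Isometry) -> np.ndarray:
        return (project_points(camera, p, pts3d) - pix).ravel()

    def rms_of(r: np.ndarray) -> float:
        return float(np.sqrt(np.mean(np.sum(r.reshape(-1, 2) ** 2, axis=1))))

    try:
        r = residual(pose)
    except ProjectionError as exc:
        raise PoseError(f"initial pose places corners behind camera: {exc}")
    rms = rms_of(r)
    lam = 1e-3
    eps = 1e-6

    for _ in range(max_iter):
        # numeric Jacobian over the local twist (3 rotation + 3 translation)
        jac = np.empty((len(r), 6))
        for j in range(6):
            delta = np.zeros(6)
            delta[j] = eps
            jac[:, j] = (residual(_perturb(pose, delta)) - residual(_perturb(pose, -delta))) / (
                2 * eps
            )
        g = jac.T @ r
        h = jac.T @ jac
        stepped = False
        for _ in range(25):
            try:
                delta = np.linalg.solve(h + lam * np.diag(np.diag(h) + 1e-12), -g)
                cand = _perturb(pose, delta)
                rc = residual(cand)
            except (np.linalg.LinAlgError, ProjectionError):
                lam *= 10
                continue
            cand_rms = rms_of(rc)
            if cand_rms <= rms:
                pose, r, stepped = cand, rc, True
                improvement = rms - cand_rms
                rms = cand_rms
                lam = max(lam / 10, 1e-12)
                break
            lam *= 10
            if lam > 1e12:
                break
        if not stepped:
            break
        if improvement < 1e-10:
            break
    else:
        raise PoseError("pose refinement did not converge", rms=rms)
    if not np.isfinite(rms):
        raise PoseError("pose refinement diverged", rms=rms)
    return RegistrationResult(pose, rms, iterations=1, converged=True,
                              correspondences_used=[len(obs)])


def _perturb(pose: Isometry, delta: np.ndarray) -> Isometry:
    r = _rodrigues(delta[:3]) @ pose.rotation
    # re-orthonormalise to keep the Isometry invariant tight
    u, _, vt = np.linalg.svd(r)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return Isometry.from_rotation_translation(r, pose.translation + delta[3:])


def compose_guidance(chain: GuidanceChain, T_cam_from_marker: Isometry) -> Isometry:
    """Pose of the planned ear in the camera frame."""
    if T_cam_from_marker.kind != "rigid":
        raise GeometryError("marker pose must be rigid")
    return (
        T_cam_from_marker
        .compose(chain.T_marker_from_splint)
        .compose(chain.T_splint_from_head)
        .compose(chain.T_head_from_earplan)
    )


def _contour_radial_samples(pts2d: np.ndarray, angles: np.ndarray):
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts2d)
    poly = pts2d[hull.vertices]
    centroid = poly.mean(axis=0)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    edges_a = poly
    edges_b = np.roll(poly, -1, axis=0)
    samples = np.empty((len(angles), 2))
    for i, d in enumerate(dirs):
        # ray centroid + t d vs each edge a + s (b - a)
        ab = edges_b - edges_a
        denom = d[0] * (-ab[:, 1]) - d[1] * (-ab[:, 0])
        rhs = edges_a - centroid
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (rhs[:, 0] * (-ab[:, 1]) - rhs[:, 1] * (-ab[:, 0])) / denom
            s = (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / denom
        valid = np.isfinite(t) & (t > 0) & (s >= -1e-12) & (s <= 1 + 1e-12)
        if not valid.any():
            samples[i] = centroid
            continue
        samples[i] = centroid + t[valid].min() * d
    return samples


def silhouette_overlay_error(
    mesh, camera: CameraModel, pose_a: Isometry, pose_b: Isometry, n_samples: int = 256
) -> float:
    """Mean 2D distance between the projected silhouette contours (px).

    Both silhouettes are taken as the convex hull of the projected
    vertices, sampled at matched polar angles about their centroids; the
    mean matched-pair distance is returned (0 for identical poses).
    """
    verts = mesh.vertices if hasattr(mesh, "vertices") else np.asarray(mesh, dtype=float)
    pa = project_points(camera, pose_a, verts)
    pb = project_points(camera, pose_b, verts)
    angles = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    sa = _contour_radial_samples(pa, angles)
    sb = _contour_radial_samples(pb, angles)
    return float(np.linalg.norm(sa - sb, axis=1).mean())


def tracking_status(marker_visible: bool, reprojection_rms: float, threshold: float = TRACKING_THRESHOLD_PX) -> str:
    """"tracked" (green frame) iff the marker is visible and rms <= threshold."""
    if threshold <= 0:
        raise GeometryError("tracking threshold must be positive")
    return "tracked" if (marker_visible and reprojection_rms <= threshold) else "lost"
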