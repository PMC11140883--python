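"""Deterministic synthetic test-data generators.

Everything the planning/registration/evaluation/AR modules consume can be
fabricated here with known ground truth: a closed head-like surface with a
parametric ear on each side (the right ear an exact mirror of the left,
making the midsagittal plane known by construction), microtia cases with
one ear removed, postoperative scans derived from a plan by a known
localised rigid perturbation plus vertex noise, and noisy cube-marker
corner observations.

The head is a radially displaced ellipsoid: nose, brow, eye and chin
bumps give masked ICP facial features to lock onto; each ear is an
elliptical protrusion carrying a helix-like ridge.  All displacement
fields depend on |x|, and the longitude grid is built exactly symmetric
under x -> -x, so left/right symmetry holds to the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, Isometry, LandmarkSet, Plane, TriMesh
from .ar import CameraModel, GuidanceChain, MarkerModel, project_points

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "make_head",
    "make_microtia_case",
    "simulate_postop",
    "synth_marker_scene",
    "VisibilityError",
]


class VisibilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic head; fixed seed -> byte-identical output."""

    seed: int = 0
    head_radii: tuple = (75.0, 95.0, 110.0)  # mm semi-axes: lateral, AP, SI
    ear_height: float = 60.0
    ear_width: float = 30.0
    ear_thickness: float = 6.0
    ear_protrusion: float = 12.0
    asymmetry: dict | None = None  # {"scale", "rotation_deg", "translation"}
    noise_sd: float = 0.0
    n_lat: int = 64
    n_lon: int = 88

    def __post_init__(self):
        for v in (*self.head_radii, self.ear_height, self.ear_width,
                  self.ear_thickness, self.ear_protrusion):
            if v <= 0:
                raise GeometryError("all dimensions must be positive")
        if self.n_lon % 2:
            raise GeometryError("n_lon must be even (mirror-symmetric longitude grid)")


@dataclass
class GroundTruth:
    """What the generator knows exactly about what it emitted."""

    sagittal_plane: Plane | None = None
    ear_pose_true: Isometry | None = None
    perturbation_applied: dict | None = None
    landmarks: LandmarkSet | None = None
    spec: SynthSpec | None = None
    ear_indices: dict = field(default_factory=dict)
    marker_pose: Isometry | None = None


# midline facial features: (direction, amplitude mm, angular width rad)
_FEATURES = [
    ((0.0, 1.0, -0.25), 18.0, 0.22),   # nose
    ((0.0, 0.85, 0.55), 6.0, 0.35),    # brow / forehead
    ((0.0, 0.8, -0.75), 8.0, 0.25),    # chin
]
_EYE_DIR = (0.38, 0.9, 0.1)            # mirrored to both sides via |x|
_EYE_AMP, _EYE_SIGMA = 3.0, 0.12
_EAR_DIR = (1.0, -0.05, 0.05)          # right-ear centre direction

_LANDMARK_DIRS = {
    "nose": (0.0, 1.0, -0.25),
    "forehead": (0.0, 0.85, 0.55),
    "chin": (0.0, 0.8, -0.75),
    "nasion": (0.0, 1.0, 0.12),
    "subnasale": (0.0, 1.0, -0.38),
    "eye_r": _EYE_DIR,
    "eye_l": (-_EYE_DIR[0], _EYE_DIR[1], _EYE_DIR[2]),
    "ear_r": _EAR_DIR,
    "ear_l": (-_EAR_DIR[0], _EAR_DIR[1], _EAR_DIR[2]),
}


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _sphere_grid(n_lat: int, n_lon: int):
    """UV-sphere directions whose longitude ring is exactly x -> -x symmetric."""
    theta = np.pi * np.arange(1, n_lat) / n_lat
    phi = 2 * np.pi * np.arange(n_lon) / n_lon
    cosp, sinp = np.cos(phi), np.sin(phi)
    for k in range(n_lon):
        m = (n_lon // 2 - k) % n_lon  # mirror partner: phi -> pi - phi
        if m < k:
            cosp[k] = -cosp[m]  # exact negation instead of a second cos() call
            sinp[k] = sinp[m]
    st, ct = np.sin(theta), np.cos(theta)
    ring = np.empty((n_lat - 1, n_lon, 3))
    ring[..., 0] = st[:, None] * cosp[None, :]
    ring[..., 1] = st[:, None] * sinp[None, :]
    ring[..., 2] = ct[:, None]
    dirs = np.vstack([[[0.0, 0.0, 1.0]], ring.reshape(-1, 3), [[0.0, 0.0, -1.0]]])

    faces = []
    def ring_idx(i, j):
        return 1 + i * n_lon + (j % n_lon)
    for j in range(n_lon):  # top cap
        faces.append([0, ring_idx(0, j), ring_idx(0, j + 1)])
    for i in range(n_lat - 2):
        for j in range(n_lon):
            a, b = ring_idx(i, j), ring_idx(i, j + 1)
            c, d = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
            faces.append([a, c, d])
            faces.append([a, d, b])
    bottom = len(dirs) - 1
    for j in range(n_lon):  # bottom cap
        faces.append([bottom, ring_idx(n_lat - 2, j + 1), ring_idx(n_lat - 2, j)])
    return dirs, np.asarray(faces, dtype=np.int64)


def _ear_profile(dirs_abs: np.ndarray, spec: SynthSpec, ear_scale_radius: float):
    """Ear displacement (mm) and normalised elliptical coordinate rho.

    Evaluated against the right-ear centre on |x| directions, so both
    sides share the identical field.
    """
    e = _unit(_EAR_DIR)
    t_up = _unit(np.array([0.0, 0.0, 1.0]) - np.dot([0.0, 0.0, 1.0], e) * e)
    t_fwd = np.cross(t_up, e)
    rel = dirs_abs - e
    u = ear_scale_radius * (rel @ t_up)    # superior offset, mm
    v = ear_scale_radius * (rel @ t_fwd)   # anterior offset, mm
    rho = np.sqrt((u / (spec.ear_height / 2)) ** 2 + (v / (spec.ear_width / 2)) ** 2)
    base = np.where(rho < 1.0, np.cos(np.clip(rho, 0, 1) * np.pi / 2) ** 1.5, 0.0)
    ridge = np.where(rho < 1.2, np.exp(-0.5 * ((rho - 0.75) / 0.12) ** 2), 0.0)
    bump = spec.ear_protrusion * base + spec.ear_thickness * ridge * (rho < 1.0)
    return bump, rho


def _radial_surface(dirs: np.ndarray, spec: SynthSpec, suppress_ear: str | None = None):
    """Radius (mm) of the head surface along each unit direction."""
    d = np.atleast_2d(dirs)
    a, b, c = spec.head_radii
    r = 1.0 / np.sqrt((d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2 + (d[:, 2] / c) ** 2)
    d_abs = d.copy()
    d_abs[:, 0] = np.abs(d_abs[:, 0])
    bump = np.zeros(len(d))
    for fdir, amp, sigma in _FEATURES:
        ang = np.arccos(np.clip(d @ _unit(fdir), -1, 1))
        bump += amp * np.exp(-0.5 * (ang / sigma) ** 2)
    ang = np.arccos(np.clip(d_abs @ _unit(_EYE_DIR), -1, 1))
    bump += _EYE_AMP * np.exp(-0.5 * (ang / _EYE_SIGMA) ** 2)

    ear_radius_scale = 1.0 / np.sqrt(
        (_unit(_EAR_DIR)[0] / a) ** 2 + (_unit(_EAR_DIR)[1] / b) ** 2 + (_unit(_EAR_DIR)[2] / c) ** 2
    )
    ear_bump, rho = _ear_profile(d_abs, spec, ear_radius_scale)
    gain = np.ones(len(d))
    if suppress_ear == "left":
        gain[d[:, 0] < 0] = 0.0
    elif suppress_ear == "right":
        gain[d[:, 0] > 0] = 0.0
    bump += ear_bump * gain
    return r + bump, rho


def make_head(spec: SynthSpec, _suppress_ear: str | None = None):
    """Closed synthetic head with two ears, landmarks, and full ground truth."""
    dirs, faces = _sphere_grid(spec.n_lat, spec.n_lon)
    radii, rho = _radial_surface(dirs, spec, suppress_ear=_suppress_ear)
    verts = dirs * radii[:, None]

    ear_indices = {
        "left": np.flatnonzero((rho < 1.0) & (dirs[:, 0] < 0)),
        "right": np.flatnonzero((rho < 1.0) & (dirs[:, 0] > 0)),
    }

    lm = {}
    for name, ld in _LANDMARK_DIRS.items():
        ld = _unit(ld)
        lm[name] = ld * _radial_surface(ld[None, :], spec, suppress_ear=_suppress_ear)[0][0]
    landmarks = LandmarkSet(lm, frame="RAS")

    ear_pose = Isometry.identity()
    perturbation = None
    if spec.asymmetry:
        asym = dict(spec.asymmetry)
        center = verts[ear_indices["right"]].mean(axis=0) if len(ear_indices["right"]) else lm["ear_r"]
        radius = 0.75 * spec.ear_height
        verts, ear_pose = _blend_transform(
            verts, center, radius,
            axis=asym.get("axis", (0.0, 0.0, 1.0)),
            angle_deg=asym.get("rotation_deg", 0.0),
            translation=asym.get("translation", (0.0, 0.0, 0.0)),
            scale=asym.get("scale", 1.0),
        )
        perturbation = asym

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        verts = verts + rng.normal(0.0, spec.noise_sd, verts.shape)

    mesh = TriMesh(verts, faces, name=f"synth_head_seed{spec.seed}")
    if mesh.signed_volume() < 0:
        mesh = TriMesh(verts, faces[:, ::-1], name=mesh.name)
    truth = GroundTruth(
        sagittal_plane=Plane(np.array([1.0, 0.0, 0.0]), 0.0),
        ear_pose_true=ear_pose,
        perturbation_applied=perturbation,
        landmarks=landmarks,
        spec=spec,
        ear_indices=ear_indices,
    )
    return mesh, landmarks, truth


def make_microtia_case(head: TriMesh, side: str, ground: GroundTruth) -> TriMesh:
    """Remove one ear (anotia emulation): the bump field on that side is
    zeroed, leaving a smooth closed cap; the healthy side is untouched."""
    if side not in ("left", "right"):
        raise GeometryError("side must be 'left' or 'right'")
    if ground.spec is None:
        raise GeometryError("ground truth does not carry the generating spec")
    mesh, _, _ = make_head(ground.spec, _suppress_ear=side)
    mesh.name = f"{head.name}_microtia_{side}"
    return mesh


def _blend_transform(verts, center, radius, axis, angle_deg, translation, scale):
    """Apply a rigid+scale perturbation to vertices near ``center`` with a
    cosine ramp over the outer 20% of ``radius``; returns the full-strength
    transform as ground truth (scale recorded separately by callers)."""
    c = np.asarray(center, dtype=float)
    axis = _unit(axis)
    t = np.asarray(translation, dtype=float)
    r_dist = np.linalg.norm(verts - c, axis=1)
    w = np.zeros(len(verts))
    inner = r_dist <= 0.8 * radius
    ramp = (r_dist > 0.8 * radius) & (r_dist < radius)
    w[inner] = 1.0
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r_dist[ramp] - 0.8 * radius) / (0.2 * radius)))

    theta = np.radians(angle_deg)
    out = verts.copy()
    null_perturbation = angle_deg == 0.0 and scale == 1.0 and not np.any(t)
    moving = w > 0
    if moving.any() and not null_perturbation:
        k = axis
        rel = verts[moving] - c
        th = w[moving] * theta  # per-vertex blended angle (Rodrigues form)
        s_fac = 1.0 + w[moving] * (scale - 1.0)
        cos_t, sin_t = np.cos(th)[:, None], np.sin(th)[:, None]
        rel_rot = rel * cos_t + np.cross(np.broadcast_to(k, rel.shape), rel) * sin_t \
            + ((rel @ k)[:, None] * k[None, :]) * (1 - cos_t)
        out[moving] = c + rel_rot * s_fac[:, None] + w[moving, None] * t

    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    full_r = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx
    pose = Isometry.from_rotation_translation(full_r, c - full_r @ c + t)
    return out, pose


def simulate_postop(
    plan_head: TriMesh,
    ear_region,
    perturbation: dict,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Postoperative scan = plan with the ear-region vertices moved by a known
    rigid(+scale) perturbation about the ear centroid, plus global noise.

    ``ear_region`` is ``(center, radius_mm)``; ``perturbation`` holds
    ``axis`` (default axial z), ``angle_deg`` (|angle| <= 30), ``translation``
    and ``scale`` (0.8..1.3).  Returns ``(mesh, GroundTruth)``.
    """
    center, radius = ear_region
    angle = float(perturbation.get("angle_deg", 0.0))
    scale = float(perturbation.get("scale", 1.0))
    if abs(angle) > 30.0:
        raise GeometryError("|angle_deg| must be <= 30")
    if not (0.8 <= scale <= 1.3):
        raise GeometryError("scale must lie in [0.8, 1.3]")
    c = np.asarray(center, dtype=float)
    in_region = np.linalg.norm(plan_head.vertices - c, axis=1) <= radius
    centroid = plan_head.vertices[in_region].mean(axis=0) if in_region.any() else c

    verts, pose = _blend_transform(
        plan_head.vertices, centroid, radius,
        axis=perturbation.get("axis", (0.0, 0.0, 1.0)),
        angle_deg=angle,
        translation=perturbation.get("translation", (0.0, 0.0, 0.0)),
        scale=scale,
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        verts = verts + rng.normal(0.0, noise_sd, verts.shape)
    mesh = TriMesh(verts, plan_head.faces.copy(), name=f"{plan_head.name}_postop")
    truth = GroundTruth(
        ear_pose_true=pose,
        perturbation_applied={
            "axis": list(_unit(perturbation.get("axis", (0.0, 0.0, 1.0)))),
            "angle_deg": angle,
            "translation": list(np.asarray(perturbation.get("translation", (0, 0, 0)), dtype=float)),
            "scale": scale,
            "noise_sd": noise_sd,
            "center": list(centroid),
            "radius": float(radius),
        },
    )
    return mesh, truth


def synth_marker_scene(
    camera: CameraModel,
    marker: MarkerModel,
    chain: GuidanceChain | None,
    true_pose: Isometry,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
):
    """Fabricate cube-corner observations a pattern detector would emit.

    Faces are back-face culled (outward normal versus the view ray to the
    face centre); every corner of a visible face must be in front of the
    camera and inside the image.  Returns ``(observations, GroundTruth)``
    with observations as ``(face_id, corner_index, (u, v))`` tuples.
    """
    rng = np.random.default_rng(seed)
    w, h = camera.image_size
    observations = []
    for fid in sorted(marker.faces):
        corners = marker.faces[fid]
        n_cam = true_pose.rotation @ marker.face_normal(fid)
        center_cam = true_pose.apply(corners.mean(axis=0))
        if float(n_cam @ center_cam) >= -1e-9:  # back-facing or grazing
            continue
        cam_pts = true_pose.apply(corners)
        if np.any(cam_pts[:, 2] <= 1e-9):
            continue
        pix = project_points(camera, true_pose, corners)
        if np.any((pix[:, 0] < 0) | (pix[:, 0] >= w) | (pix[:, 1] < 0) | (pix[:, 1] >= h)):
            continue
        if pixel_noise_sd > 0:
            pix = pix + rng.normal(0.0, pixel_noise_sd, pix.shape)
        for ci in range(4):
            observations.append((fid, ci, (float(pix[ci, 0]), float(pix[ci, 1]))))
    if not observations:
        raise VisibilityError("no cube face is fully visible in the camera frustum")
    truth = GroundTruth(marker_pose=true_pose)
    return observations, truth
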