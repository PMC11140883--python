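"""Quantitative outcome analysis of a reconstruction against its plan.

Per-vertex signed distance maps (test vertices against the reference
surface, positive outside the reference along its outward normal), region
summaries over landmark-centred spheres, caliper-style ear morphometrics
(length = 3D diameter; width = maximal extent perpendicular to the length
axis within the ear's best-fit plane), and the full postop-versus-plan
pipeline: masked ICP, distance map, region statistics, morphometric
differences, and the residual pose of the reconstructed ear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .geometry import GeometryError, Isometry, LandmarkSet, TriMesh, apply_isometry
from .proximity import SurfaceQuery
from .registration import (
    DEFAULT_MASK_RADIUS_MM,
    IcpParams,
    icp,
    mask_from_landmarks,
)
from .symmetry import crop_region

__all__ = [
    "DistanceMap",
    "MorphometricReport",
    "signed_distance_map",
    "region_summary",
    "ear_morphometrics",
    "compare_to_plan",
    "axial_rotation_angle",
    "EvaluationError",
]

DEFAULT_EAR_RADIUS_MM = 40.0
AXIAL_AXIS = np.array([0.0, 0.0, 1.0])  # superior-inferior in RAS


class EvaluationError(RuntimeError):
    def __init__(self, msg, stage=None):
        super().__init__(f"[{stage}] {msg}" if stage else msg)
        self.stage = stage


def _summary(values: np.ndarray) -> dict:
    a = np.abs(values)
    return {
        "mean_abs": float(a.mean()),
        "sd_abs": float(a.std()),  # population SD over absolute values
        "mean_signed": float(values.mean()),
        "min": float(values.min()),
        "max": float(values.max()),
    }


@dataclass
class DistanceMap:
    """Signed distances of every test vertex to the reference surface (mm)."""

    per_vertex: np.ndarray
    reference_name: str = ""
    test_name: str = ""
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.per_vertex, dtype=float)
        if not self.summary:
            self.summary = _summary(v)
        s = self.summary
        if not (s["min"] - 1e-12 <= s["mean_signed"] <= s["max"] + 1e-12):
            raise GeometryError("summary violates min <= mean_signed <= max")
        if s["mean_abs"] < abs(s["mean_signed"]) - 1e-12:
            raise GeometryError("summary violates mean_abs >= |mean_signed|")
        self.per_vertex = v


def signed_distance_map(test: TriMesh, reference: TriMesh) -> DistanceMap:
    """Distance of each test vertex to its foot point on the reference surface.

    Positive values lie outside the reference (along the nearest face's
    outward normal); degenerate reference faces are skipped.
    """
    try:
        query = SurfaceQuery(reference)
    except ValueError as exc:
        raise EvaluationError(str(exc), stage="distance_map") from exc
    signed, _, _ = query.signed_distance(test.vertices)
    return DistanceMap(signed, reference_name=reference.name, test_name=test.name)


def region_summary(dmap: DistanceMap, test: TriMesh, regions: dict) -> dict:
    """Per-region summaries over spheres ``{name: (center, radius_mm)}``.

    Vertices may belong to several regions; a sphere capturing no vertex
    yields a ``None`` summary (flagged, not an error).
    """
    if not regions:
        raise EvaluationError("no regions given", stage="region_summary")
    out = {}
    for name, (center, radius) in regions.items():
        c = np.asarray(center, dtype=float).reshape(3)
        inside = np.linalg.norm(test.vertices - c, axis=1) <= radius
        out[name] = _summary(dmap.per_vertex[inside]) if inside.any() else None
    return out


@dataclass
class MorphometricReport:
    length: float
    width: float
    length_axis: np.ndarray
    width_axis: np.ndarray

    def __post_init__(self):
        la = np.asarray(self.length_axis, dtype=float)
        wa = np.asarray(self.width_axis, dtype=float)
        if not (self.length >= self.width > 0):
            raise GeometryError("expected length >= width > 0")
        if abs(float(la @ wa)) > 1e-9:
            raise GeometryError("length and width axes must be orthogonal")
        self.length_axis, self.width_axis = la, wa


def ear_morphometrics(ear: TriMesh, width_mode: str = "max_in_plane") -> MorphometricReport:
    """Caliper length and perpendicular width of an ear surface.

    Length is the 3D diameter (maximum pairwise vertex distance, found on
    the convex hull).  Width is the extent of the vertices along the one
    direction orthogonal to the length axis inside the ear's least-squares
    best-fit plane; ``width_mode="min_perpendicular"`` instead takes the
    smallest extent over all directions orthogonal to the length axis.
    """
    v = ear.vertices
    if len(v) < 3 or np.linalg.matrix_rank(v - v.mean(axis=0), tol=1e-9) < 2:
        raise GeometryError("ear mesh is degenerate (needs 3 non-collinear vertices)")
    try:
        hull_pts = v[ConvexHull(v).vertices]
    except Exception:  # coplanar input: scipy QhullError; fall back to all points
        hull_pts = v
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = float(np.sqrt(d2[i, j]))
    length_axis = (hull_pts[j] - hull_pts[i]) / length

    centered = v - v.mean(axis=0)
    if width_mode == "max_in_plane":
        # plane normal = least-variance principal direction
        normal = np.linalg.eigh(np.cov(centered.T))[1][:, 0]
        w = np.cross(normal, length_axis)
        norm = np.linalg.norm(w)
        if norm < 1e-9:
            raise GeometryError("length axis parallel to the best-fit plane normal")
        w = w / norm
    elif width_mode == "min_perpendicular":
        # smallest extent over the circle of directions orthogonal to length
        basis = np.linalg.svd(np.eye(3) - np.outer(length_axis, length_axis))[0][:, :2]
        angles = np.linspace(0, np.pi, 720, endpoint=False)
        dirs = basis @ np.vstack([np.cos(angles), np.sin(angles)])
        proj = centered @ dirs
        extents = proj.max(axis=0) - proj.min(axis=0)
        k = int(np.argmin(extents))
        w = dirs[:, k]
    else:
        raise ValueError(f"unknown width_mode {width_mode!r}")
    # make w exactly orthogonal to the length axis
    w = w - (w @ length_axis) * length_axis
    w = w / np.linalg.norm(w)
    proj = centered @ w
    width = float(proj.max() - proj.min())
    return MorphometricReport(length, width, length_axis, w)


def axial_rotation_angle(t: Isometry, axis=AXIAL_AXIS) -> float:
    """Twist (degrees) of a rigid transform about a fixed axis (swing-twist split)."""
    r = t.rotation
    # quaternion from rotation matrix
    tr = np.trace(r)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        qw = 0.25 * s
        q = np.array([(r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s])
    else:
        k = int(np.argmax(np.diag(r)))
        i, j, l = k, (k + 1) % 3, (k + 2) % 3
        s = np.sqrt(1.0 + r[i, i] - r[j, j] - r[l, l]) * 2
        q = np.zeros(3)
        q[i] = 0.25 * s
        q[j] = (r[j, i] + r[i, j]) / s
        q[l] = (r[l, i] + r[i, l]) / s
        qw = (r[l, j] - r[j, l]) / s
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = float(q @ axis)
    twist = 2.0 * np.arctan2(proj, qw)
    ang = np.degrees(twist)
    return float((ang + 180.0) % 360.0 - 180.0)


def compare_to_plan(
    postop: TriMesh,
    plan: TriMesh,
    landmarks: LandmarkSet,
    mask_names=("eye_l", "eye_r", "forehead", "nose"),
    mask_radius: float = DEFAULT_MASK_RADIUS_MM,
    ear_center: str = "ear_r",
    ear_radius: float = DEFAULT_EAR_RADIUS_MM,
    regions: dict | None = None,
    icp_params: IcpParams | None = None,
    width_mode: str = "max_in_plane",
) -> dict:
    """Full postop-versus-plan evaluation pipeline.

    Stages: masked ICP of the postop scan onto the plan (landmark spheres
    select the stable facial surfaces) -> signed distance map of the
    registered scan against the plan (and the symmetric plan-against-scan
    map) -> per-region summaries -> ear-crop morphometrics on both models
    (differences are postop minus plan) -> residual rigid pose of the
    reconstructed ear versus the planned ear, with its axial twist.
    Returns a JSON-serialisable report including the registration.
    """
    try:
        names = [n for n in mask_names if n in landmarks]
        if not names:
            raise EvaluationError(f"no mask landmarks among {list(mask_names)}", "registration")
        mask = mask_from_landmarks(postop, landmarks, names, radius=mask_radius)
        reg = icp(postop, plan, mask=mask, params=icp_params)
    except EvaluationError:
        raise
    except Exception as exc:
        raise EvaluationError(str(exc), stage="registration") from exc

    registered = apply_isometry(postop, reg.transform)

    try:
        dmap = signed_distance_map(registered, plan)
        dmap_reverse = signed_distance_map(plan, registered)
    except Exception as exc:
        raise EvaluationError(str(exc), stage="distance_map") from exc

    region_stats = None
    if regions:
        resolved = {}
        for name, (center, radius) in regions.items():
            c = landmarks[center] if isinstance(center, str) else center
            resolved[name] = (c, radius)
        region_stats = region_summary(dmap, registered, resolved)

    try:
        ear_c = landmarks[ear_center]
        postop_ear = crop_region(registered, ear_c, ear_radius)
        plan_ear = crop_region(plan, ear_c, ear_radius)
        morph_postop = ear_morphometrics(postop_ear, width_mode=width_mode)
        morph_plan = ear_morphometrics(plan_ear, width_mode=width_mode)
    except Exception as exc:
        raise EvaluationError(str(exc), stage="morphometrics") from exc

    try:
        # residual pose of the reconstructed ear relative to the planned ear;
        # restrict to the inner crop to avoid any blended transition zone
        inner = crop_region(registered, ear_c, 0.8 * ear_radius)
        plan_ear_wide = crop_region(plan, ear_c, 1.25 * ear_radius)
        ear_reg = icp(
            inner, plan_ear_wide,
            params=IcpParams(max_iter=60, tol_mm=1e-6, reject_percentile=90.0),
        )
        residual_pose = ear_reg.transform
        axial_deg = axial_rotation_angle(residual_pose.invert())
    except Exception as exc:
        raise EvaluationError(str(exc), stage="ear_pose") from exc

    return {
        "schema_version": 1,
        "registration": {
            "matrix": [float(x) for x in reg.transform.matrix.ravel()],
            "rms_mm": reg.rms,
            "iterations": reg.iterations,
            "converged": reg.converged,
        },
        "distance_map": {
            "postop_vs_plan": dmap.summary,
            "plan_vs_postop": dmap_reverse.summary,
        },
        "regions": region_stats,
        "morphometrics": {
            "postop": {"length_mm": morph_postop.length, "width_mm": morph_postop.width},
            "plan": {"length_mm": morph_plan.length, "width_mm": morph_plan.width},
            "length_difference_mm": morph_postop.length - morph_plan.length,
            "width_difference_mm": morph_postop.width - morph_plan.width,
        },
        "ear_pose": {
            "matrix": [float(x) for x in residual_pose.matrix.ravel()],
            "axial_rotation_deg": axial_deg,
            "icp_rms_mm": ear_reg.rms,
        },
        "_distance_map_per_vertex": dmap.per_vertex,
        "_registered_postop": registered,
    }
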