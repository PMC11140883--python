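"""Signed distance maps, ear morphometrics, and the postop-vs-plan pipeline."""

import numpy as np
import pytest
import trimesh as _trimesh

from auriplan import (
    GeometryError,
    Isometry,
    SynthSpec,
    TriMesh,
    apply_isometry,
    compare_to_plan,
    ear_morphometrics,
    make_head,
    region_summary,
    signed_distance_map,
    simulate_postop,
)
from auriplan.evaluation import DistanceMap, EvaluationError, axial_rotation_angle
from conftest import random_isometry


def icosphere(radius: float, subdivisions: int = 3) -> TriMesh:
    s = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(s.vertices, dtype=float), np.asarray(s.faces))


def ellipsoid(semi_axes, n: int = 500, seed: int = 0) -> TriMesh:
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    # include the exact extreme points so analytic extents are attained
    d = np.vstack([d, np.eye(3), -np.eye(3)])
    v = d * np.asarray(semi_axes)
    hull = _trimesh.convex.convex_hull(v)
    return TriMesh(np.asarray(hull.vertices, dtype=float), np.asarray(hull.faces))


class TestSignedDistanceMap:
    def test_identical_meshes_exactly_zero(self, head_case):
        mesh, _, _ = head_case
        dmap = signed_distance_map(mesh, mesh)
        assert dmap.summary["mean_abs"] == 0.0
        assert np.all(dmap.per_vertex == 0.0)

    def test_concentric_spheres_gap(self):
        ref = icosphere(100.0, 4)
        test = icosphere(110.0, 4)
        dmap = signed_distance_map(test, ref)
        assert dmap.summary["mean_abs"] == pytest.approx(10.0, abs=0.1)
        assert np.all(dmap.per_vertex > 0)  # outside: positive sign
        inner = signed_distance_map(icosphere(90.0, 4), ref)
        assert np.all(inner.per_vertex < 0)

    def test_convergence_with_refinement(self):
        errs = []
        for sub in (2, 4):
            dmap = signed_distance_map(icosphere(110.0, sub), icosphere(100.0, sub))
            errs.append(abs(dmap.summary["mean_abs"] - 10.0))
        assert errs[1] < errs[0]

    def test_rigid_invariance(self, head_case):
        mesh, _, _ = head_case
        test = icosphere(50.0, 2)
        base = signed_distance_map(test, mesh)
        t = random_isometry(np.random.default_rng(3), 40.0)
        moved = signed_distance_map(apply_isometry(test, t), apply_isometry(mesh, t))
        assert np.abs(moved.per_vertex - base.per_vertex).max() < 1e-9

    def test_summary_invariants(self, head_case):
        mesh, _, _ = head_case
        test = icosphere(80.0, 2)
        s = signed_distance_map(test, mesh).summary
        assert s["min"] <= s["mean_signed"] <= s["max"]
        assert s["mean_abs"] >= abs(s["mean_signed"])
        assert s["mean_abs"] <= max(abs(s["min"]), abs(s["max"]))

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(GeometryError):
            DistanceMap(
                np.array([1.0, 2.0]),
                summary={"mean_abs": 0.1, "sd_abs": 0.0, "mean_signed": 1.5,
                         "min": 1.0, "max": 2.0},
            )

    def test_all_degenerate_reference_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        ref = TriMesh(v, np.array([[0, 1, 2]]))
        with pytest.raises(EvaluationError):
            signed_distance_map(icosphere(1.0, 1), ref)


class TestRegionSummary:
    def test_whole_mesh_region_equals_global(self, head_case):
        mesh, _, _ = head_case
        test = icosphere(80.0, 2)
        dmap = signed_distance_map(test, mesh)
        regions = region_summary(dmap, test, {"all": (test.centroid(), 1e6)})
        for key, value in dmap.summary.items():
            assert regions["all"][key] == pytest.approx(value, abs=1e-12)

    def test_empty_region_flagged_null(self, head_case):
        mesh, _, _ = head_case
        test = icosphere(80.0, 2)
        dmap = signed_distance_map(test, mesh)
        regions = region_summary(dmap, test, {"void": ([1e5, 1e5, 1e5], 1.0)})
        assert regions["void"] is None

    def test_perturbation_localised_to_ear_region(self, head_case):
        mesh, landmarks, _ = head_case
        postop, _ = simulate_postop(mesh, (landmarks["ear_r"], 40.0),
                                    {"angle_deg": 8.0}, noise_sd=0.0, seed=0)
        dmap = signed_distance_map(postop, mesh)
        regions = region_summary(
            dmap, postop,
            {"ear": (landmarks["ear_r"], 40.0), "nose": (landmarks["nose"], 25.0)},
        )
        assert regions["nose"]["mean_abs"] < 1e-9
        assert regions["ear"]["mean_abs"] > 0.5


class TestMorphometrics:
    def test_ellipsoid_analytic_extents(self):
        ear = ellipsoid([30.0, 15.0, 5.0])
        rep = ear_morphometrics(ear)
        assert rep.length == pytest.approx(60.0, abs=1e-9)
        assert rep.width == pytest.approx(30.0, abs=0.5)

    def test_rigid_invariance(self):
        ear = ellipsoid([30.0, 15.0, 5.0])
        base = ear_morphometrics(ear)
        t = random_isometry(np.random.default_rng(8), 100.0)
        moved = ear_morphometrics(apply_isometry(ear, t))
        assert moved.length == pytest.approx(base.length, abs=1e-6)
        assert moved.width == pytest.approx(base.width, abs=1e-6)

    def test_diameter_matches_brute_force(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=(500, 3)) * [20.0, 10.0, 4.0]
        hull = _trimesh.convex.convex_hull(v)
        mesh = TriMesh(np.asarray(hull.vertices, dtype=float), np.asarray(hull.faces))
        rep = ear_morphometrics(mesh)
        d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=2)
        assert rep.length == pytest.approx(np.sqrt(d2.max()), abs=0)

    def test_min_perpendicular_mode(self):
        ear = ellipsoid([30.0, 15.0, 5.0])
        rep = ear_morphometrics(ear, width_mode="min_perpendicular")
        assert rep.width == pytest.approx(10.0, abs=0.5)

    def test_axes_orthogonal(self):
        rep = ear_morphometrics(ellipsoid([30.0, 15.0, 5.0]))
        assert abs(float(rep.length_axis @ rep.width_axis)) < 1e-9

    def test_degenerate_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(GeometryError):
            ear_morphometrics(TriMesh(v, np.array([[0, 1, 2]])))


class TestAxialRotationAngle:
    @pytest.mark.parametrize("deg", [-20.0, -6.0, 0.0, 3.0, 17.5])
    def test_pure_axial_rotation(self, deg):
        th = np.radians(deg)
        r = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        t = Isometry.from_rotation_translation(r, [1.0, 2.0, 3.0])
        assert axial_rotation_angle(t) == pytest.approx(deg, abs=1e-9)


class TestCompareToPlan:
    def test_postop_equals_plan_all_zero(self, head_case):
        mesh, landmarks, _ = head_case
        report = compare_to_plan(mesh, mesh, landmarks)
        assert report["distance_map"]["postop_vs_plan"]["mean_abs"] < 1e-9
        assert abs(report["morphometrics"]["length_difference_mm"]) < 1e-9
        assert abs(report["morphometrics"]["width_difference_mm"]) < 1e-9
        assert abs(report["ear_pose"]["axial_rotation_deg"]) < 1e-6

    def test_inflated_ear_reads_positive(self, head_case):
        mesh, landmarks, _ = head_case
        postop, _ = simulate_postop(mesh, (landmarks["ear_r"], 40.0),
                                    {"scale": 1.1}, noise_sd=0.0, seed=1)
        report = compare_to_plan(
            postop, mesh, landmarks, regions={"ear": ("ear_r", 40.0)}
        )
        assert report["regions"]["ear"]["mean_signed"] > 0.3

    def test_axial_rotation_recovered_with_signed_lobes(self, head_case):
        mesh, landmarks, _ = head_case
        postop, _ = simulate_postop(mesh, (landmarks["ear_r"], 40.0),
                                    {"angle_deg": 6.0}, noise_sd=0.0, seed=2)
        report = compare_to_plan(postop, mesh, landmarks)
        assert report["ear_pose"]["axial_rotation_deg"] == pytest.approx(6.0, abs=0.5)
        # opposite-signed lobes on the anterior vs posterior (helix) sides
        registered = report["_registered_postop"]
        per_vertex = report["_distance_map_per_vertex"]
        center = landmarks["ear_r"]
        near_ear = np.linalg.norm(registered.vertices - center, axis=1) <= 35.0
        anterior = near_ear & (registered.vertices[:, 1] > center[1] + 5.0)
        posterior = near_ear & (registered.vertices[:, 1] < center[1] - 5.0)
        mean_ant = per_vertex[anterior].mean()
        mean_post = per_vertex[posterior].mean()
        assert mean_ant * mean_post < 0
        # elsewhere the map is flat
        far = np.linalg.norm(registered.vertices - center, axis=1) > 80.0
        assert np.abs(per_vertex[far]).mean() < 1e-6

    def test_error_labelled_with_stage(self, head_case):
        mesh, landmarks, _ = head_case
        with pytest.raises(EvaluationError) as err:
            compare_to_plan(mesh, mesh, landmarks, ear_center="no_such_landmark")
        assert err.value.stage == "morphometrics"
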