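"""Camera projection, cube-marker pose solving, guidance chain, silhouettes."""

import numpy as np
import pytest

from auriplan import (
    CameraModel,
    GeometryError,
    GuidanceChain,
    Isometry,
    MarkerModel,
    PoseError,
    ProjectionError,
    TriMesh,
    compose_guidance,
    estimate_marker_pose,
    project_points,
    silhouette_overlay_error,
    synth_marker_scene,
    tracking_status,
)
from conftest import random_isometry, random_rotation, rotation_angle_deg

FLIP = np.diag([1.0, -1.0, -1.0])  # marker +z face turned towards the camera


def frontal_pose(z=300.0):
    return Isometry.from_rotation_translation(FLIP, [0.0, 0.0, z])


def _corner_view_rotation():
    def rot(axis, deg):
        k = np.zeros(3)
        k["xyz".index(axis)] = 1.0
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        th = np.radians(deg)
        return np.eye(3) + np.sin(th) * kx + (1 - np.cos(th)) * kx @ kx

    return rot("x", 180 - 35) @ rot("y", 30) @ rot("z", 10)


class TestProjection:
    def test_on_axis_point(self):
        cam = CameraModel(fx=1000, fy=1000, cx=500, cy=500, image_size=(1000, 1000))
        uv = project_points(cam, Isometry.identity(), [[0.0, 0.0, 100.0]])
        assert np.allclose(uv, [[500.0, 500.0]])

    def test_off_axis_point(self):
        cam = CameraModel(fx=1000, fy=1000, cx=500, cy=500, image_size=(1000, 1000))
        uv = project_points(cam, Isometry.identity(), [[10.0, 0.0, 100.0]])
        assert np.allclose(uv, [[600.0, 500.0]])

    def test_radial_distortion_hand_computed(self):
        cam = CameraModel(fx=1000, fy=1000, cx=500, cy=500,
                          image_size=(1000, 1000), distortion=(0.1, 0.0))
        # normalized (0.1, 0), r^2 = 0.01, factor = 1 + 0.1*0.01 = 1.001
        uv = project_points(cam, Isometry.identity(), [[10.0, 0.0, 100.0]])
        assert np.allclose(uv, [[500.0 + 1000 * 0.1 * 1.001, 500.0]])

    def test_behind_camera_lists_indices(self):
        cam = CameraModel(fx=1000, fy=1000, cx=500, cy=500, image_size=(1000, 1000))
        with pytest.raises(ProjectionError, match=r"\[1\]"):
            project_points(cam, Isometry.identity(), [[0, 0, 10.0], [0, 0, -10.0]])


class TestMarkerModel:
    def test_cube_faces_are_squares(self, cube_marker):
        assert len(cube_marker.faces) == 6
        for fid in range(6):
            corners = cube_marker.faces[fid]
            edges = np.roll(corners, -1, axis=0) - corners
            assert np.allclose(np.linalg.norm(edges, axis=1), 30.0, atol=1e-12)

    def test_outward_normals(self, cube_marker):
        for fid in range(6):
            n = cube_marker.face_normal(fid)
            center = cube_marker.faces[fid].mean(axis=0)
            assert float(n @ center) > 0  # normal points away from cube centre

    def test_invalid_square_rejected(self):
        bad = {0: np.array([[0, 0, 0], [1, 0, 0], [1, 2, 0], [0, 1, 0]], dtype=float)}
        with pytest.raises(GeometryError):
            MarkerModel(1.0, bad)


class TestPoseEstimation:
    def test_noiseless_recovery(self, camera, cube_marker):
        rng = np.random.default_rng(0)
        recovered = 0
        for _ in range(30):
            r = random_rotation(rng) @ FLIP
            t = np.array([rng.uniform(-40, 40), rng.uniform(-25, 25), rng.uniform(200, 450)])
            pose = Isometry.from_rotation_translation(r, t)
            try:
                obs, _ = synth_marker_scene(camera, cube_marker, None, pose)
            except Exception:
                continue
            est = estimate_marker_pose(obs, cube_marker, camera)
            assert rotation_angle_deg(est.transform.rotation @ r.T) < 0.05
            assert np.linalg.norm(est.transform.translation - t) < 0.05
            assert est.rms < 1e-6
            recovered += 1
        assert recovered >= 20

    def test_frontal_translation(self, camera, cube_marker):
        obs, _ = synth_marker_scene(camera, cube_marker, None, frontal_pose())
        est = estimate_marker_pose(obs, cube_marker, camera)
        assert np.allclose(est.transform.translation, [0, 0, 300], atol=1e-6)

    def test_too_few_observations(self, camera, cube_marker):
        obs, _ = synth_marker_scene(camera, cube_marker, None, frontal_pose())
        with pytest.raises(PoseError):
            estimate_marker_pose(obs[:3], cube_marker, camera)

    def test_refinement_not_worse_than_homography_init(self, camera, cube_marker):
        from auriplan.ar import _homography_pose

        rng = np.random.default_rng(3)
        pose = Isometry.from_rotation_translation(FLIP, [15.0, -10.0, 320.0])
        obs, _ = synth_marker_scene(camera, cube_marker, None, pose,
                                    pixel_noise_sd=1.0, seed=11)
        by_face = {}
        for f, c, uv in obs:
            by_face.setdefault(f, []).append((c, uv))
        init = _homography_pose(cube_marker, camera, by_face)
        pts = np.array([cube_marker.corner(f, c) for f, c, _ in obs])
        pix = np.array([uv for _, _, uv in obs])
        init_rms = np.sqrt(
            np.mean(np.sum((project_points(camera, init, pts) - pix) ** 2, axis=1))
        )
        est = estimate_marker_pose(obs, cube_marker, camera)
        assert est.rms <= init_rms + 1e-12

    def test_noisy_pose_three_face_view(self, camera, cube_marker):
        # corner-on view: 3 visible faces, 12 corners — well-conditioned
        rng = np.random.default_rng(13)
        r = _corner_view_rotation()
        pose = Isometry.from_rotation_translation(r, [10.0, -5.0, 280.0])
        obs, _ = synth_marker_scene(camera, cube_marker, None, pose, pixel_noise_sd=0.5, seed=4)
        assert len({f for f, _, _ in obs}) == 3
        est = estimate_marker_pose(obs, cube_marker, camera)
        assert rotation_angle_deg(est.transform.rotation @ pose.rotation.T) < 1.0


class TestGuidanceChain:
    def test_identity_chain(self):
        chain = GuidanceChain(Isometry.identity(), Isometry.identity())
        out = compose_guidance(chain, Isometry.identity())
        assert np.allclose(out.matrix, np.eye(4))

    def test_chain_with_inverse_collapses(self):
        rng = np.random.default_rng(1)
        a, b = random_isometry(rng), random_isometry(rng)
        chain = GuidanceChain(a, b, Isometry.identity())
        cam_from_marker = b.invert().compose(a.invert())
        out = compose_guidance(chain, cam_from_marker)
        assert np.allclose(out.matrix, np.eye(4), atol=1e-12)

    def test_consistent_with_matrix_product_bulk(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            a, b, c, m = (random_isometry(rng) for _ in range(4))
            out = compose_guidance(GuidanceChain(a, b, c), m)
            expected = m.matrix @ a.matrix @ b.matrix @ c.matrix
            assert np.allclose(out.matrix, expected, atol=1e-9)

    def test_end_to_end_synthetic_scene(self, camera, cube_marker):
        rng = np.random.default_rng(5)
        chain = GuidanceChain(random_isometry(rng, 20.0), random_isometry(rng, 20.0))
        pose = frontal_pose(350.0)
        obs, truth = synth_marker_scene(camera, cube_marker, chain, pose)
        est = estimate_marker_pose(obs, cube_marker, camera)
        out = compose_guidance(chain, est.transform)
        expected = compose_guidance(chain, pose)
        assert np.allclose(out.matrix, expected.matrix, atol=1e-6)

    def test_reflective_marker_pose_rejected(self):
        refl = np.eye(4)
        refl[0, 0] = -1.0
        chain = GuidanceChain(Isometry.identity(), Isometry.identity())
        with pytest.raises(GeometryError):
            compose_guidance(chain, Isometry(refl, "reflective"))


def thin_plate(size=30.0):
    # a flat square at constant depth: every vertex shares one z
    v = np.array(
        [[-size, -size, 0], [size, -size, 0], [size, size, 0], [-size, size, 0]], dtype=float
    )
    return TriMesh(v, np.array([[0, 1, 2], [0, 2, 3]]))


class TestSilhouette:
    def test_identical_poses_zero(self, camera):
        mesh = thin_plate()
        pose = Isometry.from_rotation_translation(np.eye(3), [0, 0, 300.0])
        assert silhouette_overlay_error(mesh, camera, pose, pose) == 0.0

    def test_one_mm_lateral_shift(self):
        cam = CameraModel(fx=1000, fy=1000, cx=960, cy=540, image_size=(1920, 1080))
        mesh = thin_plate()
        pose_a = Isometry.from_rotation_translation(np.eye(3), [0, 0, 300.0])
        pose_b = Isometry.from_rotation_translation(np.eye(3), [1.0, 0, 300.0])
        err = silhouette_overlay_error(mesh, cam, pose_a, pose_b)
        assert err == pytest.approx(1000.0 * 1.0 / 300.0, abs=0.05)

    def test_monotone_in_perturbation(self, camera):
        mesh = thin_plate()
        pose = Isometry.from_rotation_translation(np.eye(3), [0, 0, 300.0])
        errors = []
        for mag in np.linspace(0.0, 5.0, 11):
            shifted = Isometry.from_rotation_translation(np.eye(3), [mag, 0, 300.0])
            errors.append(silhouette_overlay_error(mesh, camera, pose, shifted))
        assert all(b >= a - 1e-9 for a, b in zip(errors, errors[1:]))
        assert errors[-1] > errors[0]


class TestTrackingStatus:
    @pytest.mark.parametrize(
        "visible,rms,expected",
        [
            (True, 0.3, "tracked"),
            (False, 0.0, "lost"),
            (True, 2.0, "tracked"),  # threshold is inclusive
            (True, 2.01, "lost"),
        ],
    )
    def test_status(self, visible, rms, expected):
        assert tracking_status(visible, rms, threshold=2.0) == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(GeometryError):
            tracking_status(True, 0.1, threshold=0.0)
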