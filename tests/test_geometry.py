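import json

import numpy as np
import pytest

from endo3d.geometry import (
    CameraIntrinsics,
    DistortionCoefficients,
    FrameError,
    PixelCoord,
    Point3D,
    RigidTransform,
    backproject,
    camera_pose_from_sensor,
    distort_image,
    load_intrinsics,
    load_poses_csv,
    point_to_world,
    project,
    save_intrinsics,
    save_poses_csv,
    undistort_image,
)
from tests.conftest import random_rigid


class TestBackproject:
    def test_identity_intrinsics_origin_ray(self):
        K = CameraIntrinsics(1, 1, 0, 0, 10, 10)
        p = backproject(PixelCoord(0, 0), 5.0, K)
        assert (p.x, p.y, p.z) == (0.0, 0.0, 5.0)

    def test_principal_point_is_optical_axis(self):
        K = CameraIntrinsics(500, 500, 320, 240, 640, 480)
        p = backproject(PixelCoord(320, 240), 10.0, K)
        assert np.allclose([p.x, p.y, p.z], [0, 0, 10])

    def test_matches_explicit_matrix_inverse(self):
        K = CameraIntrinsics(500, 400, 320, 240, 640, 480)
        p = backproject(PixelCoord(420, 200), 10.0, K)
        expected = np.linalg.inv(K.K) @ (10.0 * np.array([420.0, 200.0, 1.0]))
        assert np.abs(p.as_array() - expected).max() < 1e-12
        assert p.z == 10.0

    def test_nonpositive_depth_rejected(self):
        K = CameraIntrinsics(1, 1, 0, 0, 10, 10)
        with pytest.raises(ValueError):
            backproject(PixelCoord(0, 0), 0.0, K)


class TestProject:
    def test_optical_axis_hits_principal_point(self):
        K = CameraIntrinsics(500, 500, 320, 240, 640, 480)
        px = project(Point3D(0, 0, 10, "camera"), K)
        assert (px.u, px.v) == (320.0, 240.0)

    def test_hand_evaluated_formula(self):
        K = CameraIntrinsics(500, 500, 320, 240, 640, 480)
        px = project(Point3D(2, 0, 10, "camera"), K)
        assert px.u == pytest.approx(420.0, abs=1e-12)

    def test_behind_camera_rejected(self):
        K = CameraIntrinsics(500, 500, 320, 240, 640, 480)
        with pytest.raises(ValueError):
            project(Point3D(0, 0, -1, "camera"), K)

    def test_roundtrip_in_frustum(self):
        K = CameraIntrinsics(500, 450, 320, 240, 640, 480)
        rng = np.random.default_rng(7)
        u = rng.uniform(0, 639, 1000)
        v = rng.uniform(0, 479, 1000)
        d = rng.uniform(0.01, 25, 1000)
        worst = 0.0
        for ui, vi, di in zip(u, v, d):
            px = project(backproject(PixelCoord(ui, vi), di, K), K)
            worst = max(worst, abs(px.u - ui), abs(px.v - vi))
        assert worst < 1e-9


class TestRigidTransform:
    def test_compose_requires_matching_frames(self):
        a = RigidTransform(np.eye(3), np.zeros(3), "b", "c")
        b = RigidTransform(np.eye(3), np.zeros(3), "a", "b")
        assert (a @ b).source_frame == "a"
        with pytest.raises(FrameError):
            b @ a  # noqa: B018

    def test_inverse_swaps_frames_and_undoes(self):
        rng = np.random.default_rng(3)
        T = random_rigid(rng, "a", "b")
        I = T @ T.inverse()
        assert I.source_frame == "b" and I.target_frame == "b"
        assert np.abs(I.as_matrix() - np.eye(4)).max() < 1e-12

    def test_rotations_stay_orthonormal_over_long_chains(self):
        rng = np.random.default_rng(4)
        T = RigidTransform(np.eye(3), np.zeros(3), "f", "f")
        step = random_rigid(rng, "f", "f", t_scale=1.0)
        for _ in range(1000):
            T = T @ step
        R = T.rotation
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-9

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_quaternion_roundtrip(self):
        rng = np.random.default_rng(5)
        T = random_rigid(rng, "a", "b")
        T2 = RigidTransform.from_quaternion(T.as_quaternion(), T.translation, "a", "b")
        assert np.abs(T2.rotation - T.rotation).max() < 1e-12

    def test_pose_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        poses = [random_rigid(rng, "camera", "world") for _ in range(5)]
        path = tmp_path / "poses.csv"
        save_poses_csv(path, poses)
        loaded = load_poses_csv(path)
        for a, b in zip(poses, loaded):
            assert np.abs(a.as_matrix() - b.as_matrix()).max() < 1e-12


class TestPoseChain:
    def test_identity_sensor_offset_passthrough(self):
        rng = np.random.default_rng(8)
        emTs = random_rigid(rng, "s", "em")
        cTs = RigidTransform(np.eye(3), np.zeros(3), "s", "c")
        wTc = camera_pose_from_sensor(emTs, cTs)
        assert np.abs(wTc.as_matrix() - emTs.as_matrix()).max() < 1e-12

    def test_pure_translation_offset(self):
        emTs = RigidTransform(np.eye(3), np.zeros(3), "s", "em")
        cTs = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]), "s", "c")
        wTc = camera_pose_from_sensor(emTs, cTs)
        assert np.allclose(wTc.translation, [-1, -2, -3])
        assert np.allclose(wTc.rotation, np.eye(3))

    def test_rearrangement_identity(self):
        rng = np.random.default_rng(9)
        emTs = random_rigid(rng, "s", "em")
        cTs = random_rigid(rng, "s", "c")
        wTc = camera_pose_from_sensor(emTs, cTs)
        # wTc . cTs must reproduce emTs
        recomposed = wTc.as_matrix() @ cTs.as_matrix()
        assert np.abs(recomposed - emTs.as_matrix()).max() < 1e-12

    def test_frame_label_mismatch_raises(self):
        rng = np.random.default_rng(10)
        with pytest.raises(FrameError):
            camera_pose_from_sensor(
                random_rigid(rng, "x", "y"), random_rigid(rng, "s", "c")
            )

    def test_point_to_world_matches_dense_matrix_oracle(self):
        rng = np.random.default_rng(11)
        emTs = random_rigid(rng, "s", "em")
        cTs = random_rigid(rng, "s", "c")
        p_c = Point3D(*rng.normal(scale=5, size=3), "camera")
        p_w = point_to_world(p_c, emTs, cTs)
        hom = (
            emTs.as_matrix()
            @ np.linalg.inv(cTs.as_matrix())
            @ np.append(p_c.as_array(), 1.0)
        )
        assert np.abs(p_w.as_array() - hom[:3]).max() < 1e-12

    def test_world_point_equals_pose_applied_to_camera_point(self):
        rng = np.random.default_rng(12)
        emTs = random_rigid(rng, "s", "em")
        cTs = random_rigid(rng, "s", "c")
        p_c = Point3D(1.0, -2.0, 3.0, "camera")
        via_chain = point_to_world(p_c, emTs, cTs)
        via_pose = camera_pose_from_sensor(emTs, cTs).apply(p_c)
        assert np.abs(via_chain.as_array() - via_pose.as_array()).max() == 0.0


class TestDistortion:
    def test_zero_coefficients_identity(self, K64):
        rng = np.random.default_rng(13)
        img = rng.random((64, 64, 3))
        out = undistort_image(img, K64, DistortionCoefficients())
        assert np.array_equal(out, img)

    def test_uniform_image_invariant(self, K64):
        img = np.full((64, 64, 3), 0.37)
        out = undistort_image(img, K64, DistortionCoefficients(k1=-0.2, p1=0.01))
        assert np.abs(out - 0.37).max() < 1e-12

    def test_dimension_mismatch_rejected(self, K64):
        with pytest.raises(ValueError):
            undistort_image(np.zeros((32, 32, 3)), K64, DistortionCoefficients())

    def test_distort_then_undistort_restores_straight_edges(self):
        # checkerboard edges must come back straight to sub-pixel tolerance
        K = CameraIntrinsics(100.0, 100.0, 64.0, 64.0, 128, 128)
        xx, yy = np.meshgrid(np.arange(128), np.arange(128))
        board = (((xx // 16) + (yy // 16)) % 2).astype(float)
        img = np.stack([board] * 3, axis=-1)
        dist = DistortionCoefficients(k1=-0.1)
        restored = undistort_image(distort_image(img, K, dist), K, dist)
        # locate the vertical edge near column 64 on several rows by
        # sub-pixel interpolation of the 0.5 crossing, then fit a line
        cols = []
        for row in range(20, 108, 8):
            seg = restored[row, 56:72, 0]
            crossings = np.nonzero(np.diff(seg > 0.5))[0]
            i = crossings[0]
            frac = (0.5 - seg[i]) / (seg[i + 1] - seg[i])
            cols.append(56 + i + frac)
        cols = np.array(cols)
        rows = np.arange(20, 108, 8, dtype=float)
        fit = np.polyfit(rows, cols, 1)
        residual = np.abs(cols - np.polyval(fit, rows))
        assert residual.max() < 0.5


def test_intrinsics_json_roundtrip(tmp_path):
    K = CameraIntrinsics(500, 450, 320, 240, 640, 480)
    dist = DistortionCoefficients(-0.1, 0.01, 0.001, -0.002, 0.0005)
    path = tmp_path / "intrinsics.json"
    save_intrinsics(path, K, dist)
    doc = json.loads(path.read_text())
    assert doc["dist"] == [-0.1, 0.01, 0.001, -0.002, 0.0005]
    K2, dist2 = load_intrinsics(path)
    assert K2 == K and dist2 == dist
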