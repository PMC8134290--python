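import numpy as np
import pytest

from endo3d.calibration import (
    DegenerateConfigurationError,
    EMSensorModel,
    PointCorrespondences,
    UnobservableError,
    em_sample,
    hand_eye_calibrate,
    hand_eye_residuals,
    rigid_register_svd,
    sample_sensor_stream,
)
from endo3d.geometry import RigidTransform, camera_pose_from_sensor
from tests.conftest import random_rigid


def _rotation_angle(R: np.ndarray) -> float:
    # quaternion magnitude stays accurate for angles near zero, where the
    # arccos-of-trace formula bottoms out around 1e-8
    from scipy.spatial.transform import Rotation

    return float(Rotation.from_matrix(R).magnitude())


def _noncoplanar_points(rng, n=6):
    pts = rng.uniform(-20, 20, size=(n, 3))
    pts[0] += [5, 0, 0]  # nudge away from accidental degeneracy
    return pts


class TestRigidRegistration:
    def test_identity_correspondence(self):
        rng = np.random.default_rng(0)
        x = _noncoplanar_points(rng)
        res = rigid_register_svd(PointCorrespondences.from_arrays(x, x))
        assert np.abs(res.transform.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(res.transform.translation).max() < 1e-12
        assert res.rms_residual < 1e-12

    def test_pure_translation(self):
        rng = np.random.default_rng(1)
        x = _noncoplanar_points(rng)
        res = rigid_register_svd(
            PointCorrespondences.from_arrays(x, x + [1.0, 2.0, 3.0])
        )
        assert np.allclose(res.transform.translation, [1, 2, 3])
        assert res.rms_residual < 1e-12

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_generate_and_recover_noiseless(self, seed):
        rng = np.random.default_rng(seed)
        x = _noncoplanar_points(rng)
        T = random_rigid(rng, "model", "em")
        y = x @ T.rotation.T + T.translation
        res = rigid_register_svd(PointCorrespondences.from_arrays(x, y))
        rot_err = _rotation_angle(res.transform.rotation.T @ T.rotation)
        assert rot_err < 1e-9
        assert np.abs(res.transform.translation - T.translation).max() < 1e-9

    def test_noisy_rms_bounded(self):
        sigma = 0.2
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = _noncoplanar_points(rng)
            T = random_rigid(rng, "model", "em")
            y = x @ T.rotation.T + T.translation + rng.normal(0, sigma, x.shape)
            res = rigid_register_svd(PointCorrespondences.from_arrays(x, y))
            assert res.rms_residual <= 3 * sigma

    def test_rms_matches_per_point_residuals(self):
        rng = np.random.default_rng(6)
        x = _noncoplanar_points(rng)
        y = x + rng.normal(0, 0.5, x.shape)
        res = rigid_register_svd(PointCorrespondences.from_arrays(x, y))
        assert res.rms_residual == pytest.approx(
            np.sqrt(np.mean(res.per_point_residuals**2)), abs=1e-12
        )

    def test_left_invariance_of_residual(self):
        rng = np.random.default_rng(7)
        x = _noncoplanar_points(rng)
        y = x + rng.normal(0, 0.3, x.shape)
        base = rigid_register_svd(PointCorrespondences.from_arrays(x, y))
        G = random_rigid(rng, "em", "em")
        xg = x @ G.rotation.T + G.translation
        yg = y @ G.rotation.T + G.translation
        moved = rigid_register_svd(PointCorrespondences.from_arrays(xg, yg))
        assert moved.rms_residual == pytest.approx(base.rms_residual, abs=1e-9)

    def test_too_few_points_rejected(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateConfigurationError):
            rigid_register_svd(PointCorrespondences.from_arrays(x, x))

    def test_collinear_points_rejected(self):
        x = np.outer(np.arange(6.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateConfigurationError):
            rigid_register_svd(PointCorrespondences.from_arrays(x, x))

    def test_reflection_corrected_to_proper_rotation(self):
        # mirrored targets tempt the unconstrained solution toward det = -1
        rng = np.random.default_rng(8)
        x = _noncoplanar_points(rng)
        y = x.copy()
        y[:, 2] *= -1
        res = rigid_register_svd(PointCorrespondences.from_arrays(x, y))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        x = _noncoplanar_points(rng)
        corr = PointCorrespondences.from_arrays(x, x + 1.0)
        path = tmp_path / "corr.csv"
        corr.save_csv(path)
        loaded = PointCorrespondences.load_csv(path)
        xs, ys = loaded.arrays()
        assert np.abs(xs - x).max() < 1e-12


def _motion_pairs(rng, cTs: RigidTransform, n=10):
    """Simulated (sensor motion, camera motion) pairs consistent with cTs."""
    X = cTs.as_matrix()
    pairs = []
    for _ in range(n):
        B = random_rigid(rng, "c", "c", t_scale=5.0).as_matrix()  # camera motion
        A = np.linalg.inv(X) @ B @ X  # sensor motion
        pairs.append(
            (
                RigidTransform.from_matrix(A, "s", "s"),
                RigidTransform.from_matrix(B, "c", "c"),
            )
        )
    return pairs


class TestHandEye:
    def test_equal_motions_give_identity(self):
        rng = np.random.default_rng(10)
        I = RigidTransform(np.eye(3), np.zeros(3), "s", "c")
        pairs = _motion_pairs(rng, I, n=5)
        X = hand_eye_calibrate(pairs)
        assert np.abs(X.as_matrix() - np.eye(4)).max() < 1e-9

    def test_generate_and_recover_noiseless(self):
        rng = np.random.default_rng(11)
        true_X = random_rigid(rng, "s", "c", t_scale=2.0)
        pairs = _motion_pairs(rng, true_X, n=10)
        X = hand_eye_calibrate(pairs)
        assert _rotation_angle(X.rotation.T @ true_X.rotation) < 1e-6
        assert np.abs(X.translation - true_X.translation).max() < 1e-6
        assert hand_eye_residuals(pairs, X).max() < 1e-9

    def test_single_pair_unobservable(self):
        rng = np.random.default_rng(12)
        pairs = _motion_pairs(rng, RigidTransform(np.eye(3), np.zeros(3), "s", "c"), 1)
        with pytest.raises(UnobservableError):
            hand_eye_calibrate(pairs)

    def test_parallel_axes_unobservable(self):
        from scipy.spatial.transform import Rotation

        cTs = RigidTransform(np.eye(3), np.array([2.0, 0, 0]), "s", "c")
        X = cTs.as_matrix()
        pairs = []
        for ang in (0.3, 0.6, 0.9):
            Rz = Rotation.from_rotvec([0, 0, ang]).as_matrix()
            B = np.eye(4)
            B[:3, :3] = Rz
            B[:3, 3] = [1.0, 2.0, 0.5]
            A = np.linalg.inv(X) @ B @ X
            pairs.append(
                (
                    RigidTransform.from_matrix(A, "s", "s"),
                    RigidTransform.from_matrix(B, "c", "c"),
                )
            )
        with pytest.raises(UnobservableError):
            hand_eye_calibrate(pairs)


class TestEMSensor:
    def test_zero_noise_consistency_with_pose_chain(self):
        rng = np.random.default_rng(13)
        sensor = EMSensorModel()
        pose = random_rigid(rng, "camera", "world")
        emTs = em_sample(sensor, pose, t=0.2)
        recovered = camera_pose_from_sensor(emTs, sensor.true_cTs)
        assert np.abs(recovered.as_matrix() - pose.as_matrix()).max() < 1e-12

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(14)
        sensor = EMSensorModel(
            translation_noise_sd=0.5, rotation_noise_sd=0.01, rng_seed=42
        )
        pose = random_rigid(rng, "camera", "world")
        a = em_sample(sensor, pose, t=0.5)
        b = em_sample(sensor, pose, t=0.5)
        assert np.array_equal(a.as_matrix(), b.as_matrix())

    def test_translation_noise_statistics(self):
        rng = np.random.default_rng(15)
        sigma = 0.5
        sensor = EMSensorModel(translation_noise_sd=sigma, rng_seed=7)
        pose = random_rigid(rng, "camera", "world")
        clean = em_sample(EMSensorModel(rng_seed=7), pose, 0.0).translation
        devs = []
        for i in range(10_000):
            s = em_sample(sensor, pose, t=i * 0.02)
            devs.extend(s.translation - clean)
        sd = np.std(devs)
        assert abs(sd - sigma) / sigma < 0.05

    def test_latency_shifts_delivery_timestamps(self):
        rng = np.random.default_rng(16)
        sensor = EMSensorModel(latency=100.0)
        poses = [random_rigid(rng, "camera", "world") for _ in range(3)]
        stream = sample_sensor_stream(sensor, poses, [0.0, 0.02, 0.04])
        assert [t for t, _ in stream] == pytest.approx([0.1, 0.12, 0.14])
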