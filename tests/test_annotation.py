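import numpy as np
import pytest

from endo3d import simulator as sim
from endo3d.annotation import (
    Annotation,
    PipelineStageError,
    StreamBundle,
    NoDataError,
    load_annotations,
    pipeline_step,
    place_annotation,
    reproject_annotation,
    save_annotations,
    synchronize_streams,
)
from endo3d.geometry import (
    CameraIntrinsics,
    DistortionCoefficients,
    PixelCoord,
    Point3D,
    RigidTransform,
    project,
)
from endo3d.simulator import DepthMap, normalize_depth, scene_cast
from tests.conftest import random_rigid

IDENTITY_W = RigidTransform(np.eye(3), np.zeros(3), "camera", "world")


class TestPlacement:
    def test_far_plane_on_optical_axis(self, K64):
        depth = DepthMap(np.zeros((64, 64)), "normalized")  # 0 = far = 25 mm
        a = place_annotation(PixelCoord(32, 32), depth, K64, IDENTITY_W)
        assert np.allclose(a.p_w.as_array(), [0, 0, 25])
        assert a.p_w.frame == "world"

    def test_out_of_bounds_pixel_rejected(self, K64):
        depth = DepthMap(np.zeros((64, 64)), "normalized")
        with pytest.raises(IndexError):
            place_annotation(PixelCoord(64, 10), depth, K64, IDENTITY_W)

    def test_oracle_placement_lands_on_the_wall(
        self, airway_scene, short_trajectory, K64
    ):
        from tests.conftest import point_mesh_distance

        pose = short_trajectory.poses[0]
        frame = sim.render_frame(airway_scene, pose, K64)
        a = place_annotation(
            PixelCoord(32, 16), normalize_depth(frame.depth), K64, pose
        )
        dist = point_mesh_distance(airway_scene.mesh, a.p_w.as_array()[None, :])
        step = (sim.DEPTH_FAR_MM - sim.DEPTH_NEAR_MM) / 65535
        # float depth map here, so the only slack is ray-cast numerics
        assert dist[0] < 2 * step

    def test_same_pose_consecutive_frames_identical(
        self, airway_scene, short_trajectory, K64
    ):
        pose = short_trajectory.poses[0]
        frame = sim.render_frame(airway_scene, pose, K64)
        n = normalize_depth(frame.depth)
        a = place_annotation(PixelCoord(30, 20), n, K64, pose)
        b = place_annotation(PixelCoord(30, 20), n, K64, pose)
        assert np.array_equal(a.p_w.as_array(), b.p_w.as_array())

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            Annotation(Point3D(0, 0, 10, "world"), radius=0.0)


class TestReprojection:
    def test_apparent_radius_arithmetic(self):
        K = CameraIntrinsics(500, 500, 320, 240, 640, 480)
        a = Annotation(Point3D(0, 0, 10, "world"), radius=0.5)
        px, apparent, visible = reproject_annotation(a, IDENTITY_W, K)
        assert (px.u, px.v) == (320.0, 240.0)
        assert apparent == pytest.approx(25.0)
        assert visible

    def test_behind_camera_invisible(self):
        K = CameraIntrinsics(500, 500, 320, 240, 640, 480)
        a = Annotation(Point3D(0, 0, -5, "world"))
        px, _, visible = reproject_annotation(a, IDENTITY_W, K)
        assert not visible and px is None

    def test_halving_distance_doubles_apparent_size(self):
        K = CameraIntrinsics(500, 500, 320, 240, 640, 480)
        near = reproject_annotation(
            Annotation(Point3D(0, 0, 5, "world"), 0.5), IDENTITY_W, K
        )[1]
        far = reproject_annotation(
            Annotation(Point3D(0, 0, 10, "world"), 0.5), IDENTITY_W, K
        )[1]
        assert near == pytest.approx(2 * far)

    def test_place_then_reproject_returns_same_pixel(
        self, airway_scene, short_trajectory, K64
    ):
        pose = short_trajectory.poses[2]
        frame = sim.render_frame(airway_scene, pose, K64)
        a = place_annotation(
            PixelCoord(40, 25), normalize_depth(frame.depth), K64, pose
        )
        px, _, _ = reproject_annotation(a, pose, K64)
        assert abs(px.u - 40) < 1e-6 and abs(px.v - 25) < 1e-6

    def test_anchoring_across_views(self, airway_scene, K64):
        # place in one view; the reprojection in other views must coincide
        # with the direct projection of the true surface point
        traj = sim.generate_trajectory(
            airway_scene, 6, speed=2.0, sample_rate=10, seed=5
        )
        pose0 = traj.poses[0]
        frame0 = sim.render_frame(airway_scene, pose0, K64)
        px0 = PixelCoord(32, 20)
        a = place_annotation(px0, normalize_depth(frame0.depth), K64, pose0)
        d_cam = np.array([(px0.u - K64.cx) / K64.fx, (px0.v - K64.cy) / K64.fy, 1.0])
        t, _, hit = scene_cast(
            airway_scene, pose0.translation, (pose0.rotation @ d_cam)[None, :]
        )
        assert hit[0]
        p_true = pose0.translation + t[0] * (pose0.rotation @ d_cam)
        for pose in traj.poses[1:]:
            px, _, _ = reproject_annotation(a, pose, K64)
            ref = project(pose.inverse().apply(Point3D.from_array(p_true, "world")), K64)
            assert abs(px.u - ref.u) < 0.5 and abs(px.v - ref.v) < 0.5


class TestPipeline:
    def _oracle_predictor(self, scene, pose, K):
        frame = sim.render_frame(scene, pose, K)
        gt = normalize_depth(frame.depth)
        return frame, (lambda rgb: gt)

    def test_oracle_bypass_returns_ground_truth(
        self, airway_scene, short_trajectory, K64
    ):
        pose = short_trajectory.poses[1]
        frame, predictor = self._oracle_predictor(airway_scene, pose, K64)
        from endo3d.calibration import EMSensorModel, em_sample

        sensor = EMSensorModel()
        emTs = em_sample(sensor, pose, 0.0)
        result = pipeline_step(
            frame.rgb, emTs, sensor.true_cTs, K64,
            DistortionCoefficients(), None, predictor,
        )
        assert np.array_equal(
            result.depth.values, normalize_depth(frame.depth).values
        )
        assert np.abs(result.wTc.as_matrix() - pose.as_matrix()).max() < 1e-9

    def test_stage_timing_log_complete(self, airway_scene, short_trajectory, K64):
        pose = short_trajectory.poses[0]
        frame, predictor = self._oracle_predictor(airway_scene, pose, K64)
        from endo3d.calibration import EMSensorModel, em_sample

        sensor = EMSensorModel()
        result = pipeline_step(
            frame.rgb, em_sample(sensor, pose, 0.0), sensor.true_cTs, K64,
            DistortionCoefficients(), lambda img: img, predictor,
        )
        assert [s for s, _ in result.stage_times] == [
            "undistort", "style_transfer", "depth", "pose",
        ]

    def test_missing_depth_predictor_is_a_stage_error(self, K64):
        from endo3d.calibration import EMSensorModel, em_sample

        sensor = EMSensorModel()
        emTs = em_sample(sensor, IDENTITY_W, 0.0)
        with pytest.raises(PipelineStageError):
            pipeline_step(
                np.zeros((64, 64, 3)), emTs, sensor.true_cTs, K64,
                DistortionCoefficients(), None, None,
            )


class TestStreamSync:
    def _bundle(self, offsets=(0.0, 0.0, 0.0)):
        times = np.arange(0, 1.0, 0.02)  # 50 Hz
        pose = [(float(t), i) for i, t in enumerate(times)]
        video = [(float(t), i) for i, t in enumerate(times)]
        depth = [(float(t), i) for i, t in enumerate(times)]
        return StreamBundle(pose, video, depth, *offsets)

    def test_identical_timestamps_zero_offsets(self):
        b = self._bundle()
        (tp, p), (tv, v), (td, d) = synchronize_streams(b, 0.5)
        assert p == v == d == 25
        assert tp == tv == td == pytest.approx(0.5)

    def test_offsets_align_to_depth_latency(self):
        # depth arrives 100 ms after capture; delaying pose+video by 100 ms
        # re-aligns all three streams to the same capture instant (t - 100 ms)
        times = np.arange(0, 1.0, 0.02)
        pose = [(float(t), i) for i, t in enumerate(times)]
        video = [(float(t), i) for i, t in enumerate(times)]
        depth = [(float(t) + 0.1, i) for i, t in enumerate(times)]  # delivery
        b = StreamBundle(pose, video, depth, 100.0, 100.0, 0.0)
        (_, p), (_, v), (_, d) = synchronize_streams(b, 0.5)
        assert p == v == d == 20  # all captured at 0.40 s

    def test_misaligned_offsets_differ_by_exactly_the_mismatch(self):
        b = self._bundle(offsets=(60.0, 0.0, 0.0))
        (tp, p), (tv, v), _ = synchronize_streams(b, 0.5)
        # a 60 ms extra delay on the pose stream at a 50 Hz grid leaves the
        # returned capture timestamps 60 ms apart (3 samples)
        assert tv - tp == pytest.approx(0.06)
        assert v - p == 3

    def test_query_before_first_sample(self):
        b = self._bundle(offsets=(100.0, 0.0, 0.0))
        with pytest.raises(NoDataError):
            synchronize_streams(b, 0.05)

    def test_nonmonotone_stream_rejected(self):
        with pytest.raises(ValueError):
            StreamBundle([(0.0, 1), (0.0, 2)], [(0.0, 1)], [(0.0, 1)])


def test_annotation_json_roundtrip(tmp_path):
    anns = [
        Annotation(Point3D(1.0, 2.0, 3.0, "world"), 0.5, "polyp", 7),
        Annotation(Point3D(-1.0, 0.5, 9.0, "world"), 1.0, "margin", 12),
    ]
    path = tmp_path / "annotations.json"
    save_annotations(path, anns)
    loaded = load_annotations(path)
    assert loaded == anns
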