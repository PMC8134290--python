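"""Accuracy metrics and the annotation-stability protocol.

Accuracy is scored frame-wise between predicted and ground-truth depth maps
with NRMSE (RMS error over the ground-truth value range) and SSIM.

The stability protocol tracks a fixed world-frame target on the airway wall
while the camera moves forward and backward along the lumen: per sample the
"reference depth" is the target's z-coordinate in the true camera frame and
the "predicted depth" is whatever the depth source reports at the target's
projected pixel, converted to millimetres.  The trace's mean absolute error
(MAE) summarizes temporal consistency of the depth source.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calibration import EMSensorModel, em_sample
from .geometry import (
    CameraIntrinsics,
    PixelCoord,
    Point3D,
    RigidTransform,
    camera_pose_from_sensor,
    project,
)
from .io import read_depth_png
from .nn.functional import gaussian_kernel_1d
from .simulator import (
    AirwayScene,
    DepthMap,
    DEPTH_FAR_MM,
    DEPTH_NEAR_MM,
    Trajectory,
    denormalize_value,
    render_frame,
    scene_cast,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyReport",
    "StabilityTrace",
    "nrmse",
    "ssim",
    "evaluate_accuracy",
    "evaluate_stability",
    "OracleDepthProvider",
    "NetworkDepthProvider",
]


# ----------------------------------------------------------------------
# Metrics
# ----------------------------------------------------------------------

def nrmse(pred: DepthMap, gt: DepthMap) -> float:
    """RMS error normalized by the ground-truth map's value range."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if pred.mode != gt.mode:
        raise ValueError(f"mode mismatch: {pred.mode} vs {gt.mode}")
    x, y = gt.values, pred.values
    rng = float(x.max() - x.min())
    if rng == 0.0:
        raise ValueError("ground-truth range is zero; NRMSE undefined")
    return float(np.sqrt(np.mean((x - y) ** 2)) / rng)


def ssim(
    pred: DepthMap | np.ndarray,
    gt: DepthMap | np.ndarray,
    data_range: float = 1.0,
    sigma: float = 1.5,
    truncate: float = 3.5,
) -> float:
    """Mean structural similarity with a Gaussian window (11 x 11 default).

    Population (not sample) local moments and stabilizing constants
    C1 = (0.01 L)^2, C2 = (0.03 L)^2; the SSIM map is averaged over the
    fully-windowed interior, so the value is boundary-mode independent.
    """
    x = pred.values if isinstance(pred, DepthMap) else np.asarray(pred, float)
    y = gt.values if isinstance(gt, DepthMap) else np.asarray(gt, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    k = gaussian_kernel_1d(sigma, truncate)
    r = (len(k) - 1) // 2
    if min(x.shape) < 2 * r + 1:
        raise ValueError(
            f"window {2 * r + 1} larger than image {x.shape}"
        )

    def blur(a):
        out = ndimage.correlate1d(a, k, axis=0, mode="nearest")
        return ndimage.correlate1d(out, k, axis=1, mode="nearest")

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x, mu_y = blur(x), blur(y)
    sxx = blur(x * x) - mu_x**2
    syy = blur(y * y) - mu_y**2
    sxy = blur(x * y) - mu_x * mu_y
    s = ((2 * mu_x * mu_y + c1) * (2 * sxy + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    )
    return float(s[r:-r, r:-r].mean())


# ----------------------------------------------------------------------
# Accuracy over datasets
# ----------------------------------------------------------------------

@dataclass
class AccuracyReport:
    frame_indices: list[int]
    nrmse_values: np.ndarray
    ssim_values: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)

    @property
    def nrmse_mean(self) -> float:
        return float(np.mean(self.nrmse_values))

    @property
    def nrmse_sd(self) -> float:
        return float(np.std(self.nrmse_values))

    @property
    def ssim_mean(self) -> float:
        return float(np.mean(self.ssim_values))

    @property
    def ssim_sd(self) -> float:
        return float(np.std(self.ssim_values))

    def summary(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "nrmse_mean": self.nrmse_mean,
            "nrmse_sd": self.nrmse_sd,
            "ssim_mean": self.ssim_mean,
            "ssim_sd": self.ssim_sd,
        }

    def save(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            rows = ["frame_index,nrmse,ssim"]
            for i, nv, sv in zip(
                self.frame_indices, self.nrmse_values, self.ssim_values
            ):
                rows.append(f"{i},{nv:.10g},{sv:.10g}")
            Path(csv_path).write_text("\n".join(rows) + "\n")
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2))


_DEPTH_RE = re.compile(r"(\d+)\.png$")


def _index_depth_files(directory) -> dict[int, Path]:
    out = {}
    for p in sorted(Path(directory).glob("*.png")):
        m = _DEPTH_RE.search(p.name)
        if m and "rgb" not in p.name:
            out[int(m.group(1))] = p
    return out


def evaluate_accuracy(pred_dir, gt_dir) -> AccuracyReport:
    """Frame-paired NRMSE/SSIM between two directories of depth PNGs.

    Files pair by the integer index in their names; metrics are computed on
    the normalized maps.  Missing partners raise with the offending indices.
    """
    pred_files = _index_depth_files(pred_dir)
    gt_files = _index_depth_files(gt_dir)
    missing = sorted(set(pred_files) ^ set(gt_files))
    if missing:
        raise ValueError(f"unpaired frame indices: {missing}")
    if not pred_files:
        raise ValueError("no depth PNGs found")
    idx = sorted(pred_files)
    nr, ss = [], []
    for i in idx:
        pred = read_depth_png(pred_files[i])
        gt = read_depth_png(gt_files[i])
        nr.append(nrmse(pred, gt))
        ss.append(ssim(pred, gt))
    return AccuracyReport(idx, np.array(nr), np.array(ss))


# ----------------------------------------------------------------------
# Stability protocol
# ----------------------------------------------------------------------

class OracleDepthProvider:
    """Ground-truth depth straight from the simulator's ray caster.

    Answers depth queries at arbitrary sub-pixel positions by casting the
    exact ray through the queried pixel; an optional constant bias supports
    protocol self-tests.
    """

    def __init__(self, scene: AirwayScene, K: CameraIntrinsics, bias_mm: float = 0.0):
        self.scene, self.K, self.bias_mm = scene, K, bias_mm

    def depth_at(self, pose: RigidTransform, pixel: PixelCoord) -> float:
        d_cam = np.array(
            [
                (pixel.u - self.K.cx) / self.K.fx,
                (pixel.v - self.K.cy) / self.K.fy,
                1.0,
            ]
        )
        d_world = pose.rotation @ d_cam
        t, _, hit = scene_cast(
            self.scene, pose.translation, d_world[None, :], pose.rotation[:, 2]
        )
        if not hit[0]:
            return DEPTH_FAR_MM + self.bias_mm
        return float(np.clip(t[0], DEPTH_NEAR_MM, DEPTH_FAR_MM)) + self.bias_mm


class NetworkDepthProvider:
    """Depth from the learned pipeline: render RGB, (optionally) style
    transfer, predict a normalized map, sample the nearest pixel."""

    def __init__(self, scene, K, predict_fn, lights=None, translator=None):
        self.scene, self.K = scene, K
        self.predict_fn = predict_fn  # rgb -> normalized DepthMap
        self.lights = lights
        self.translator = translator  # optional rgb -> rgb

    def depth_at(self, pose: RigidTransform, pixel: PixelCoord) -> float:
        frame = render_frame(self.scene, pose, self.K, self.lights)
        rgb = frame.rgb
        if self.translator is not None:
            rgb = self.translator(rgb)
        dmap = self.predict_fn(rgb)
        u = int(np.clip(round(pixel.u), 0, self.K.width - 1))
        v = int(np.clip(round(pixel.v), 0, self.K.height - 1))
        return float(denormalize_value(dmap.values[v, u]))


@dataclass
class StabilityTrace:
    timestamps: np.ndarray
    reference_mm: np.ndarray
    predicted_mm: np.ndarray
    reference_euclidean_mm: np.ndarray
    excluded_frames: list[int] = field(default_factory=list)

    @property
    def mae(self) -> float:
        return float(np.mean(np.abs(self.reference_mm - self.predicted_mm)))

    def save_csv(self, path) -> None:
        rows = ["t,reference_mm,predicted_mm"]
        for t, r, p in zip(self.timestamps, self.reference_mm, self.predicted_mm):
            rows.append(f"{t:.6f},{r:.10g},{p:.10g}")
        Path(path).write_text("\n".join(rows) + "\n")

    def plot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(self.timestamps, self.reference_mm, label="reference depth")
        ax.plot(self.timestamps, self.predicted_mm, label="predicted depth")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("depth (mm)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def evaluate_stability(
    scene: AirwayScene,
    target_point: Point3D,
    trajectory: Trajectory,
    depth_provider,
    sensor: EMSensorModel,
    K: CameraIntrinsics,
) -> StabilityTrace:
    """Track a known world-frame wall point through a forward-backward pass.

    Per sample the camera pose is recovered from the (possibly noisy) EM
    sensor reading through the hand-eye transform; the target is projected
    with that pose to find its pixel, the depth source is queried there, and
    the result is compared against the target's true z-depth.  Samples where
    the target leaves the view are excluded with a warning.
    """
    if target_point.frame != "world":
        raise ValueError("target must be a world-frame point")
    ts, refs, preds, eucl, excluded = [], [], [], [], []
    for i, (pose_true, t) in enumerate(zip(trajectory.poses, trajectory.timestamps)):
        emTs = em_sample(sensor, pose_true, float(t))
        pose_est = camera_pose_from_sensor(emTs, sensor.true_cTs)
        p_cam_est = pose_est.inverse().apply(target_point)
        if p_cam_est.z <= 0:
            excluded.append(i)
            continue
        px = project(p_cam_est, K)
        if not (0 <= px.u <= K.width - 1 and 0 <= px.v <= K.height - 1):
            excluded.append(i)
            continue
        p_cam_true = pose_true.inverse().apply(target_point)
        ts.append(float(t))
        refs.append(p_cam_true.z)
        eucl.append(float(np.linalg.norm(p_cam_true.as_array())))
        preds.append(depth_provider.depth_at(pose_est, px))
    if excluded:
        logger.warning(
            "stability target out of view in %d/%d frames; excluded",
            len(excluded),
            len(trajectory),
        )
    return StabilityTrace(
        np.array(ts), np.array(refs), np.array(preds), np.array(eucl), excluded
    )
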