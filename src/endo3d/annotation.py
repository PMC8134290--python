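"""Depth-anchored 3D annotation: placement, reprojection, stream sync.

An annotation is a small sphere fixed to a world-frame surface point.  It is
placed once from a cursor pixel: the pixel's predicted depth d lifts it to a
camera-frame point ``p_c = K^-1 * d * [u, v, 1]^T``, which the tracked
camera pose sends to world coordinates ``p_w``.  Every subsequent frame
re-projects ``p_w`` through the current pose, so the marker sticks to the
anatomy instead of the screen, and its apparent radius ``fx * r / z`` shrinks
with distance, a depth-perception cue for the viewer.

The world frame is identified with the EM tracker frame (the sensor pose
stream is consumed directly as a world pose): ``WORLD_IS_EM_FRAME`` below is
that identity, stated once.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import (
    CameraIntrinsics,
    DistortionCoefficients,
    PixelCoord,
    Point3D,
    RigidTransform,
    backproject,
    camera_pose_from_sensor,
    project,
    undistort_image,
)
from .simulator import DepthMap, denormalize_value

__all__ = [
    "WORLD_IS_EM_FRAME",
    "Annotation",
    "StreamBundle",
    "PipelineResult",
    "pipeline_step",
    "place_annotation",
    "reproject_annotation",
    "synchronize_streams",
    "save_annotations",
    "load_annotations",
]

# The EM tracking frame doubles as the virtual world frame.
WORLD_IS_EM_FRAME = RigidTransform.identity("world")

DEFAULT_RADIUS_MM = 0.5


@dataclass(frozen=True)
class Annotation:
    """Spherical marker anchored at a world-frame position."""

    p_w: Point3D
    radius: float = DEFAULT_RADIUS_MM
    label: str = ""
    created_at_frame: int = 0

    def __post_init__(self) -> None:
        if self.p_w.frame != "world":
            raise ValueError("annotation position must be world-frame")
        if not self.radius > 0:
            raise ValueError("annotation radius must be positive")


def save_annotations(path, annotations: list[Annotation]) -> None:
    doc = [
        {
            "label": a.label,
            "p_w": list(a.p_w.as_array()),
            "radius": a.radius,
            "created_at_frame": a.created_at_frame,
        }
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_annotations(path) -> list[Annotation]:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        Annotation(
            Point3D.from_array(d["p_w"], "world"),
            d["radius"],
            d["label"],
            d["created_at_frame"],
        )
        for d in doc
    ]


# ----------------------------------------------------------------------
# Per-frame pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineResult:
    undistorted: np.ndarray
    depth: DepthMap  # normalized
    wTc: RigidTransform
    stage_times: list[tuple[str, float]] = field(default_factory=list)


class PipelineStageError(RuntimeError):
    pass


def pipeline_step(
    frame: np.ndarray,
    emTs: RigidTransform,
    cTs: RigidTransform,
    K: CameraIntrinsics,
    dist: DistortionCoefficients,
    translator=None,
    depth_predictor=None,
) -> PipelineResult:
    """One frame of the live pipeline.

    undistort -> real-to-virtual translation -> depth prediction, plus the
    camera pose from the sensor reading.  ``translator`` is an RGB -> RGB
    callable (None = identity, the oracle bypass); ``depth_predictor`` is an
    RGB -> normalized DepthMap callable (e.g. a trained model's predict, or
    a ground-truth lookup in oracle mode).  Deterministic in its inputs.
    """
    times: list[tuple[str, float]] = []

    def timed(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except Exception as exc:  # annotate which stage failed
            raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc
        times.append((stage, time.perf_counter() - t0))
        return out

    undist = timed("undistort", undistort_image, frame, K, dist)
    styled = (
        timed("style_transfer", translator, undist)
        if translator is not None
        else undist
    )
    if depth_predictor is None:
        raise PipelineStageError("stage 'depth' failed: no depth predictor given")
    depth = timed("depth", depth_predictor, styled)
    if depth.mode != "normalized":
        raise PipelineStageError("stage 'depth' failed: predictor must return "
                                 "a normalized DepthMap")
    wTc = timed("pose", camera_pose_from_sensor, emTs, cTs)
    return PipelineResult(undist, depth, wTc, times)


# ----------------------------------------------------------------------
# Placement / reprojection
# ----------------------------------------------------------------------

def place_annotation(
    pixel: PixelCoord,
    depth: DepthMap,
    K: CameraIntrinsics,
    wTc: RigidTransform,
    radius: float = DEFAULT_RADIUS_MM,
    label: str = "",
    created_at_frame: int = 0,
) -> Annotation:
    """Anchor a marker at the surface point under a cursor pixel.

    Depth is sampled at the nearest pixel (bilinear interpolation across a
    depth discontinuity would fabricate a 3D point between surfaces), then
    converted to millimetres and lifted through the pose chain.
    """
    if depth.mode != "normalized":
        raise ValueError("place_annotation expects a normalized depth map")
    H, W = depth.shape
    u, v = int(round(pixel.u)), int(round(pixel.v))
    if not (0 <= u < W and 0 <= v < H):
        raise IndexError(f"pixel ({pixel.u}, {pixel.v}) outside {W}x{H} image")
    d = float(denormalize_value(depth.values[v, u]))
    p_c = backproject(pixel, d, K)
    p_w = wTc.apply(p_c)
    return Annotation(p_w, radius, label, created_at_frame)


def reproject_annotation(
    a: Annotation, wTc: RigidTransform, K: CameraIntrinsics
) -> tuple[PixelCoord | None, float, bool]:
    """Render the anchored sphere into a view.

    Returns (center pixel, apparent radius in px, visible).  The center is
    the projection of ``p_w`` through the inverse pose; apparent radius is
    ``fx * radius / z``.  Behind-camera or out-of-bounds markers come back
    with ``visible=False`` (pixel is still reported when z > 0).
    """
    p_c = wTc.inverse().apply(a.p_w)
    if p_c.z <= 0:
        return None, 0.0, False
    px = project(p_c, K)
    apparent = K.fx * a.radius / p_c.z
    visible = (0 <= px.u <= K.width - 1) and (0 <= px.v <= K.height - 1)
    return px, float(apparent), visible


# ----------------------------------------------------------------------
# Stream synchronization
# ----------------------------------------------------------------------

@dataclass
class StreamBundle:
    """Timestamped pose / video / depth streams with per-stream delay offsets.

    Offsets (ms, >= 0) are added to each stream's timestamps before lookup;
    choosing pose/video offsets equal to the depth stream's processing
    latency aligns all three to the same capture instant.
    """

    pose_stream: list[tuple[float, RigidTransform]]
    video_stream: list[tuple[float, np.ndarray]]
    depth_stream: list[tuple[float, DepthMap]]
    pose_offset_ms: float = 0.0
    video_offset_ms: float = 0.0
    depth_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        for name, stream in (
            ("pose", self.pose_stream),
            ("video", self.video_stream),
            ("depth", self.depth_stream),
        ):
            tt = [t for t, _ in stream]
            if any(b <= a for a, b in zip(tt, tt[1:])):
                raise ValueError(f"{name} stream timestamps must increase")
        if min(self.pose_offset_ms, self.video_offset_ms, self.depth_offset_ms) < 0:
            raise ValueError("stream offsets must be >= 0")


class NoDataError(LookupError):
    pass


def _latest(stream, offset_ms: float, query_time: float):
    times = np.array([t for t, _ in stream]) + offset_ms / 1000.0
    i = int(np.searchsorted(times, query_time, side="right")) - 1
    if i < 0:
        raise NoDataError(
            f"no sample at or before t={query_time} (first at {times[0]})"
        )
    return stream[i][0], stream[i][1]  # raw (undelayed) timestamp + payload


def synchronize_streams(bundle: StreamBundle, query_time: float):
    """Latest-sample alignment of the three streams at a query time.

    Each stream contributes its newest sample whose delayed timestamp
    (timestamp + offset) does not exceed the query; returns
    ((t_pose, pose), (t_video, frame), (t_depth, depth)) with the effective
    timestamps.
    """
    return (
        _latest(bundle.pose_stream, bundle.pose_offset_ms, query_time),
        _latest(bundle.video_stream, bundle.video_offset_ms, query_time),
        _latest(bundle.depth_stream, bundle.depth_offset_ms, query_time),
    )
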