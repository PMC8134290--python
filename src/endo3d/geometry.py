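"""Camera model and rigid-pose algebra.

Conventions
-----------
* Right-handed camera frame: +z along the optical axis into the scene,
  +x to the right, +y down.
* Pixels: ``u`` is the column, ``v`` the row, origin at the top-left,
  pixel centers at integer coordinates.  Both may be fractional.
* All lengths are millimetres.
* Depth ``d`` of a pixel is the camera-frame z-coordinate (z-depth) of the
  surface point, so back-projection is ``p_c = K^-1 * d * [u, v, 1]^T`` and
  the z-component of the result equals ``d`` exactly.
* A :class:`RigidTransform` labelled ``target<-source`` maps coordinates of a
  point expressed in the *source* frame into the *target* frame.

The world frame is identified with the electromagnetic (EM) tracker frame:
the tracked sensor pose stream is interpreted directly as a world-frame
pose, so the camera pose is ``wTc = emTs . cTs^-1`` where ``emTs`` is the
streamed sensor pose and ``cTs`` the fixed hand-eye transform between the
camera and the sensor rigidly attached to the endoscope tip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "CameraIntrinsics",
    "DistortionCoefficients",
    "RigidTransform",
    "PixelCoord",
    "Point3D",
    "FrameError",
    "backproject",
    "project",
    "distort_points",
    "undistort_points",
    "undistort_image",
    "distort_image",
    "camera_pose_from_sensor",
    "point_to_world",
]

_ORTHO_TOL = 1e-9


class FrameError(ValueError):
    """Raised when transform/point frame labels do not chain."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "width": self.width,
            "height": self.height,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            width=int(d["width"]),
            height=int(d["height"]),
        )


@dataclass(frozen=True)
class DistortionCoefficients:
    """Brown–Conrady lens distortion: radial k1,k2,k3 and tangential p1,p2."""

    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.p1, self.p2, self.k3)
        if not all(np.isfinite(vals)):
            raise ValueError("distortion coefficients must be finite")

    @property
    def is_identity(self) -> bool:
        return self.k1 == self.k2 == self.k3 == self.p1 == self.p2 == 0.0

    def as_array(self) -> np.ndarray:
        """OpenCV-style ordering [k1, k2, p1, p2, k3]."""
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])


def save_intrinsics(path, K: CameraIntrinsics, dist: DistortionCoefficients) -> None:
    doc = K.to_dict()
    doc["dist"] = list(dist.as_array())
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_intrinsics(path) -> tuple[CameraIntrinsics, DistortionCoefficients]:
    with open(path) as fh:
        doc = json.load(fh)
    dist = doc.pop("dist", [0.0] * 5)
    k1, k2, p1, p2, k3 = (list(dist) + [0.0] * 5)[:5]
    return CameraIntrinsics.from_dict(doc), DistortionCoefficients(k1, k2, p1, p2, k3)


@dataclass(frozen=True)
class PixelCoord:
    """Sub-pixel image location; u = column, v = row."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("pixel coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v])


@dataclass(frozen=True)
class Point3D:
    """A 3D point tagged with the frame its coordinates are expressed in."""

    x: float
    y: float
    z: float
    frame: str = "camera"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("point coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @classmethod
    def from_array(cls, a, frame: str) -> "Point3D":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)


@dataclass(frozen=True)
class RigidTransform:
    """6-DoF rigid transform ``target<-source`` (rotation then translation).

    ``apply`` maps source-frame coordinates to target-frame coordinates:
    ``x_target = R @ x_source + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source_frame: str = "source"
    target_frame: str = "target"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (|R'R-I|={err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        # Re-orthonormalize if slightly off so long composition chains stay SO(3).
        if err > _ORTHO_TOL:
            U, _, Vt = np.linalg.svd(R)
            object.__setattr__(self, "rotation", U @ Vt)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls, frame: str = "world") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), frame, frame)

    @classmethod
    def from_matrix(cls, T, source_frame="source", target_frame="target"):
        T = np.asarray(T, dtype=float)
        return cls(T[:3, :3], T[:3, 3], source_frame, target_frame)

    @classmethod
    def from_quaternion(cls, qxyzw, t, source_frame="source", target_frame="target"):
        R = Rotation.from_quat(np.asarray(qxyzw, dtype=float)).as_matrix()
        return cls(R, t, source_frame, target_frame)

    # -- accessors ----------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        return T

    def as_quaternion(self) -> np.ndarray:
        """Unit quaternion (x, y, z, w)."""
        return Rotation.from_matrix(self.rotation).as_quat()

    # -- algebra ------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        if self.source_frame != other.target_frame:
            raise FrameError(
                f"cannot compose {self.target_frame}<-{self.source_frame} with "
                f"{other.target_frame}<-{other.source_frame}"
            )
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            other.source_frame,
            self.target_frame,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(
            Rt, -Rt @ self.translation, self.target_frame, self.source_frame
        )

    def apply(self, point: Point3D) -> Point3D:
        if point.frame != self.source_frame:
            raise FrameError(
                f"transform expects points in frame {self.source_frame!r}, "
                f"got {point.frame!r}"
            )
        p = self.rotation @ point.as_array() + self.translation
        return Point3D.from_array(p, self.target_frame)

    def apply_array(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized frame change for an (N, 3) array (no label checks)."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation


# ----------------------------------------------------------------------
# Projection
# ----------------------------------------------------------------------

def backproject(pixel: PixelCoord, d: float, K: CameraIntrinsics) -> Point3D:
    """Lift a pixel with z-depth ``d`` (mm) to a camera-frame 3D point.

    Implements ``p_c = K^-1 * d * [u, v, 1]^T``; the returned z equals ``d``.
    """
    if not d > 0:
        raise ValueError(f"depth must be positive, got {d}")
    x = (pixel.u - K.cx) / K.fx * d
    y = (pixel.v - K.cy) / K.fy * d
    return Point3D(x, y, float(d), "camera")


def project(p: Point3D, K: CameraIntrinsics) -> PixelCoord:
    """Project a camera-frame point (z > 0) to pixel coordinates."""
    if p.frame != "camera":
        raise FrameError(f"project expects a camera-frame point, got {p.frame!r}")
    if not p.z > 0:
        raise ValueError(f"point is behind the camera (z={p.z})")
    return PixelCoord(K.fx * p.x / p.z + K.cx, K.fy * p.y / p.z + K.cy)


def camera_pose_from_sensor(
    emTs: RigidTransform, cTs: RigidTransform
) -> RigidTransform:
    """Camera pose in the world(=EM) frame: ``wTc = emTs . cTs^-1``."""
    if (emTs.target_frame, emTs.source_frame) != ("em", "s"):
        raise FrameError(
            f"emTs must be em<-s, got {emTs.target_frame}<-{emTs.source_frame}"
        )
    if (cTs.target_frame, cTs.source_frame) != ("c", "s"):
        raise FrameError(
            f"cTs must be c<-s, got {cTs.target_frame}<-{cTs.source_frame}"
        )
    wTc = emTs @ cTs.inverse()
    return RigidTransform(wTc.rotation, wTc.translation, "camera", "world")


def point_to_world(
    p_c: Point3D, emTs: RigidTransform, cTs: RigidTransform
) -> Point3D:
    """Express a camera-frame point in world coordinates via the pose chain."""
    if p_c.frame != "camera":
        raise FrameError(f"expected a camera-frame point, got {p_c.frame!r}")
    wTc = camera_pose_from_sensor(emTs, cTs)
    return wTc.apply(p_c)


# ----------------------------------------------------------------------
# Distortion
# ----------------------------------------------------------------------

def _distort_normalized(xy: np.ndarray, dist: DistortionCoefficients) -> np.ndarray:
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (dist.k1 + r2 * (dist.k2 + r2 * dist.k3))
    xd = x * radial + 2.0 * dist.p1 * x * y + dist.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + dist.p1 * (r2 + 2.0 * y * y) + 2.0 * dist.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def distort_points(
    pts: np.ndarray, K: CameraIntrinsics, dist: DistortionCoefficients
) -> np.ndarray:
    """Map ideal (undistorted) pixel coordinates to distorted ones."""
    pts = np.asarray(pts, dtype=float)
    xy = (pts - [K.cx, K.cy]) / [K.fx, K.fy]
    xyd = _distort_normalized(xy, dist)
    return xyd * [K.fx, K.fy] + [K.cx, K.cy]


def undistort_points(
    pts: np.ndarray,
    K: CameraIntrinsics,
    dist: DistortionCoefficients,
    iterations: int = 20,
) -> np.ndarray:
    """Invert the Brown–Conrady map by fixed-point iteration."""
    pts = np.asarray(pts, dtype=float)
    target = (pts - [K.cx, K.cy]) / [K.fx, K.fy]
    xy = target.copy()
    for _ in range(iterations):
        xy = xy + (target - _distort_normalized(xy, dist))
    return xy * [K.fx, K.fy] + [K.cx, K.cy]


def _resample(img: np.ndarray, src_uv: np.ndarray) -> np.ndarray:
    """Bilinear resample of an H x W (x C) image at (u, v) source positions."""
    coords = [src_uv[..., 1].ravel(), src_uv[..., 0].ravel()]  # (row, col)
    if img.ndim == 2:
        out = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        return out.reshape(img.shape)
    chans = [
        ndimage.map_coordinates(img[..., c], coords, order=1, mode="nearest")
        for c in range(img.shape[-1])
    ]
    return np.stack([c.reshape(img.shape[:2]) for c in chans], axis=-1)


def _check_dims(img: np.ndarray, K: CameraIntrinsics) -> None:
    if img.shape[0] != K.height or img.shape[1] != K.width:
        raise ValueError(
            f"image is {img.shape[1]}x{img.shape[0]} but intrinsics say "
            f"{K.width}x{K.height}"
        )


def undistort_image(
    img: np.ndarray, K: CameraIntrinsics, dist: DistortionCoefficients
) -> np.ndarray:
    """Resample a distorted image onto the ideal pinhole grid.

    Each undistorted output pixel is filled by sampling the input at the
    position the lens would have bent it to (the forward distortion map).
    All-zero coefficients return the input unchanged.
    """
    img = np.asarray(img)
    _check_dims(img, K)
    if dist.is_identity:
        return img.copy()
    vv, uu = np.meshgrid(
        np.arange(K.height, dtype=float), np.arange(K.width, dtype=float),
        indexing="ij",
    )
    grid = np.stack([uu, vv], axis=-1)
    src = distort_points(grid.reshape(-1, 2), K, dist).reshape(grid.shape)
    return _resample(img.astype(float), src).astype(img.dtype, copy=False)


def distort_image(
    img: np.ndarray, K: CameraIntrinsics, dist: DistortionCoefficients
) -> np.ndarray:
    """Apply lens distortion to an ideal image (inverse of undistort_image)."""
    img = np.asarray(img)
    _check_dims(img, K)
    if dist.is_identity:
        return img.copy()
    vv, uu = np.meshgrid(
        np.arange(K.height, dtype=float), np.arange(K.width, dtype=float),
        indexing="ij",
    )
    grid = np.stack([uu, vv], axis=-1)
    src = undistort_points(grid.reshape(-1, 2), K, dist).reshape(grid.shape)
    return _resample(img.astype(float), src).astype(img.dtype, copy=False)


# ----------------------------------------------------------------------
# Pose stream serialization: frame_index, tx, ty, tz, qx, qy, qz, qw
# ----------------------------------------------------------------------

def save_poses_csv(path, poses: list[RigidTransform]) -> None:
    rows = ["frame_index,tx,ty,tz,qx,qy,qz,qw"]
    for i, T in enumerate(poses):
        t = T.translation
        q = T.as_quaternion()
        rows.append(
            f"{i},{t[0]:.17g},{t[1]:.17g},{t[2]:.17g},"
            f"{q[0]:.17g},{q[1]:.17g},{q[2]:.17g},{q[3]:.17g}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def load_poses_csv(path, source_frame="camera", target_frame="world"):
    poses = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("frame_index"):
            raise ValueError(f"unexpected pose CSV header in {path}")
        for line in fh:
            if not line.strip():
                continue
            vals = [float(v) for v in line.split(",")]
            poses.append(
                RigidTransform.from_quaternion(
                    vals[4:8], vals[1:4], source_frame, target_frame
                )
            )
    return poses
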