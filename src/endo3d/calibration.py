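"""Rigid registration, hand-eye calibration, and a simulated EM sensor.

Registration aligns the virtual anatomy model to the physical phantom frame:
given paired landmarks {x_i} in the model frame and {y_i} in the EM frame, it
finds the rigid transform (R, t) minimizing sum_i ||R x_i + t - y_i||^2 by
the SVD of the centered cross-covariance (Arun/Kabsch), with the reflection
correction that flips the smallest singular direction when det < 0.

Hand-eye calibration recovers the fixed camera<-sensor transform cTs from
paired relative motions (AX = XB) with the Tsai-Lenz two-step solution:
rotation first from the rotation-axis relations, then translation from a
linear least-squares system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Point3D, RigidTransform, camera_pose_from_sensor

__all__ = [
    "PointCorrespondences",
    "RegistrationResult",
    "EMSensorModel",
    "DegenerateConfigurationError",
    "UnobservableError",
    "rigid_register_svd",
    "hand_eye_calibrate",
    "em_sample",
    "sample_sensor_stream",
]


class DegenerateConfigurationError(ValueError):
    """Point configuration does not determine a unique rigid transform."""


class UnobservableError(ValueError):
    """Motion set does not determine the hand-eye transform."""


@dataclass
class PointCorrespondences:
    """Paired landmarks: model-frame {x_i} vs EM-frame {y_i}."""

    model_points: list[Point3D]
    em_points: list[Point3D]

    def __post_init__(self) -> None:
        if len(self.model_points) != len(self.em_points):
            raise ValueError("point lists must have equal length")

    @property
    def n(self) -> int:
        return len(self.model_points)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([p.as_array() for p in self.model_points])
        y = np.array([p.as_array() for p in self.em_points])
        return x, y

    @classmethod
    def from_arrays(cls, x, y) -> "PointCorrespondences":
        return cls(
            [Point3D.from_array(p, "model") for p in np.asarray(x, dtype=float)],
            [Point3D.from_array(p, "em") for p in np.asarray(y, dtype=float)],
        )

    def save_csv(self, path) -> None:
        x, y = self.arrays()
        rows = ["set,point_id,x,y,z"]
        for i, p in enumerate(x):
            rows.append(f"model,{i},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}")
        for i, p in enumerate(y):
            rows.append(f"em,{i},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")

    @classmethod
    def load_csv(cls, path) -> "PointCorrespondences":
        model: dict[int, np.ndarray] = {}
        em: dict[int, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline().strip()
            if header != "set,point_id,x,y,z":
                raise ValueError(f"unexpected correspondence header: {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                which, pid, x, y, z = line.strip().split(",")
                dest = model if which == "model" else em
                dest[int(pid)] = np.array([float(x), float(y), float(z)])
        ids = sorted(model)
        if ids != sorted(em):
            raise ValueError("model/em point ids do not pair up")
        return cls.from_arrays([model[i] for i in ids], [em[i] for i in ids])


@dataclass
class RegistrationResult:
    transform: RigidTransform  # em<-model
    rms_residual: float
    per_point_residuals: np.ndarray


def rigid_register_svd(corr: PointCorrespondences) -> RegistrationResult:
    """Least-squares rigid registration of paired point sets via SVD.

    Requires at least 3 non-collinear pairs; enforces a proper rotation
    (det = +1) by sign-flipping the smallest singular direction.
    """
    if corr.n < 3:
        raise DegenerateConfigurationError(
            f"need at least 3 correspondences, got {corr.n}"
        )
    x, y = corr.arrays()
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # Collinearity check: the second singular value of the centered model
    # points vanishes iff all points lie on one line.
    sv = np.linalg.svd(xc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("model points are collinear")
    H = xc.T @ yc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = y.mean(axis=0) - R @ x.mean(axis=0)
    res = np.linalg.norm(x @ R.T + t - y, axis=1)
    return RegistrationResult(
        transform=RigidTransform(R, t, "model", "em"),
        rms_residual=float(np.sqrt(np.mean(res**2))),
        per_point_residuals=res,
    )


# ----------------------------------------------------------------------
# Hand-eye calibration (Tsai-Lenz)
# ----------------------------------------------------------------------

def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def _rot_to_modified_rodrigues(R: np.ndarray) -> np.ndarray:
    """Tsai's rotation parameterization p = 2 sin(theta/2) * axis."""
    q = np.empty(3)
    # axis-angle via the skew-symmetric part; stable away from theta = pi,
    # which calibration motions should avoid anyway
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(w) / 2.0  # sin(theta)
    c = (np.trace(R) - 1.0) / 2.0  # cos(theta)
    theta = np.arctan2(s, c)
    if s < 1e-12:
        return np.zeros(3)
    axis = w / (2.0 * s)
    q = 2.0 * np.sin(theta / 2.0) * axis
    return q


def _modified_rodrigues_to_rot(p: np.ndarray) -> np.ndarray:
    n2 = float(p @ p)
    a = np.sqrt(4.0 - n2)
    return (1.0 - n2 / 2.0) * np.eye(3) + 0.5 * (
        np.outer(p, p) + a * _skew(p)
    )


def _solve_ax_xb(As: list[np.ndarray], Bs: list[np.ndarray]) -> np.ndarray:
    """Solve A_i X = X B_i for 4x4 homogeneous motions (Tsai-Lenz)."""
    if len(As) < 2:
        raise UnobservableError("need at least 2 motion pairs")
    M = []
    rhs = []
    axes = []
    for A, B in zip(As, Bs):
        pa = _rot_to_modified_rodrigues(A[:3, :3])
        pb = _rot_to_modified_rodrigues(B[:3, :3])
        M.append(_skew(pa + pb))
        rhs.append(pb - pa)
        if np.linalg.norm(pa) > 1e-10:
            axes.append(pa / np.linalg.norm(pa))
    if len(axes) < 2 or _axes_parallel(axes):
        raise UnobservableError(
            "rotation axes are parallel or motions are pure translations; "
            "the hand-eye rotation is unobservable"
        )
    M = np.vstack(M)
    rhs = np.concatenate(rhs)
    p_prime, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    p = 2.0 * p_prime / np.sqrt(1.0 + float(p_prime @ p_prime))
    Rx = _modified_rodrigues_to_rot(p)
    # Translation: (R_A - I) t_X = R_X t_B - t_A
    C = np.vstack([A[:3, :3] - np.eye(3) for A in As])
    d = np.concatenate([Rx @ B[:3, 3] - A[:3, 3] for A, B in zip(As, Bs)])
    tx, *_ = np.linalg.lstsq(C, d, rcond=None)
    X = np.eye(4)
    X[:3, :3] = Rx
    X[:3, 3] = tx
    return X


def _axes_parallel(axes: list[np.ndarray], tol: float = 1e-8) -> bool:
    a0 = axes[0]
    return all(np.linalg.norm(np.cross(a0, a)) < tol for a in axes[1:])


def hand_eye_calibrate(
    motion_pairs: list[tuple[RigidTransform, RigidTransform]],
) -> RigidTransform:
    """Recover cTs from paired (sensor-motion, camera-motion) transforms.

    Each pair holds the sensor's relative motion ``A_i`` between two poses of
    the tracked stream and the camera's relative motion ``B_i`` between the
    same two instants.  Since ``emTs = wTc . cTs`` at every instant, camera
    and sensor motions are conjugate through the fixed hand-eye transform:
    ``B_i . cTs = cTs . A_i``.  Needs >= 2 pairs with non-parallel rotation
    axes, otherwise :class:`UnobservableError`.
    """
    if len(motion_pairs) < 2:
        raise UnobservableError("need at least 2 motion pairs")
    As = [b.as_matrix() for _, b in motion_pairs]  # camera motions
    Bs = [a.as_matrix() for a, _ in motion_pairs]  # sensor motions
    X = _solve_ax_xb(As, Bs)
    return RigidTransform.from_matrix(X, source_frame="s", target_frame="c")


def hand_eye_residuals(
    motion_pairs: list[tuple[RigidTransform, RigidTransform]],
    cTs: RigidTransform,
) -> np.ndarray:
    """Frobenius residual ||B_i X - X A_i|| per motion pair."""
    X = cTs.as_matrix()
    out = []
    for a, b in motion_pairs:
        out.append(np.linalg.norm(b.as_matrix() @ X - X @ a.as_matrix()))
    return np.array(out)


# ----------------------------------------------------------------------
# Simulated EM sensor
# ----------------------------------------------------------------------

@dataclass
class EMSensorModel:
    """A 6-DoF pose sensor rigidly attached to the endoscope tip.

    The default hand-eye offset places the sensor 2 mm off the camera's
    optical axis, the mounting geometry this system assumes to limit
    error propagation from imperfect hand-eye calibration.
    """

    true_cTs: RigidTransform = field(
        default_factory=lambda: RigidTransform(
            np.eye(3), np.array([2.0, 0.0, 0.0]), "s", "c"
        )
    )
    translation_noise_sd: float = 0.0  # mm
    rotation_noise_sd: float = 0.0  # radians
    latency: float = 0.0  # ms
    sample_rate: float = 50.0  # Hz
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.translation_noise_sd < 0 or self.rotation_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")


def _small_rotation(rng: np.random.Generator, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.eye(3)
    w = rng.normal(0.0, sd, size=3)
    theta = np.linalg.norm(w)
    if theta < 1e-15:
        return np.eye(3)
    K = _skew(w / theta)
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K


def em_sample(
    sensor: EMSensorModel,
    true_camera_pose: RigidTransform,
    t: float = 0.0,
) -> RigidTransform:
    """One noisy sensor reading ``emTs`` for a true camera pose ``wTc``.

    Constructed so that with zero noise
    ``camera_pose_from_sensor(em_sample(...), true_cTs)`` returns the true
    camera pose exactly: ``emTs = wTc . cTs`` (world and EM frames coincide).
    Noise is seeded deterministically from (rng_seed, sample time), so a
    stream re-sampled with the same seed is bit-identical.
    """
    emTs_clean = RigidTransform(
        true_camera_pose.rotation,
        true_camera_pose.translation,
        "camera",
        "em",
    ) @ RigidTransform(
        sensor.true_cTs.rotation, sensor.true_cTs.translation, "s", "camera"
    )
    rng = np.random.default_rng(
        [sensor.rng_seed & 0x7FFFFFFF, int(round(t * 1e6)) & 0x7FFFFFFF]
    )
    dR = _small_rotation(rng, sensor.rotation_noise_sd)
    dt = (
        rng.normal(0.0, sensor.translation_noise_sd, size=3)
        if sensor.translation_noise_sd > 0
        else np.zeros(3)
    )
    return RigidTransform(
        dR @ emTs_clean.rotation, emTs_clean.translation + dt, "s", "em"
    )


def sample_sensor_stream(
    sensor: EMSensorModel,
    poses: list[RigidTransform],
    timestamps: np.ndarray,
) -> list[tuple[float, RigidTransform]]:
    """Sample emTs along a trajectory; delivery timestamps include latency."""
    out = []
    delay = sensor.latency / 1000.0
    for T, t in zip(poses, np.asarray(timestamps, dtype=float)):
        out.append((t + delay, em_sample(sensor, T, t)))
    return out
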