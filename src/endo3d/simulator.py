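"""Procedural endoscopic scene simulator with ground-truth z-depth.

Stands in for a game-engine rendering pipeline: a curved tubular airway
lumen with a uniform light-red wall (mimicking nasal mucosa without
patient-specific texture), a pinhole camera travelling along the lumen, and
two point lights co-moving with the camera whose irradiance falls off with
the inverse square of distance — the photometric cue a depth-from-shading
network relies on.

Depth semantics: every depth value is the camera-frame z-coordinate of the
surface point seen through the pixel center (z-depth, not ray length), in
millimetres, clamped to the observable span [0.01, 25] mm.  The normalized
form maps 25 mm (far) to 0 and 0.01 mm (near) to 1, linearly in metric depth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh

from .geometry import CameraIntrinsics, RigidTransform, save_poses_csv, save_intrinsics, DistortionCoefficients

__all__ = [
    "DEPTH_NEAR_MM",
    "DEPTH_FAR_MM",
    "DepthMap",
    "normalize_depth",
    "denormalize_depth",
    "LightSource",
    "AirwaySceneParams",
    "AirwayScene",
    "Trajectory",
    "RenderedFrame",
    "generate_airway_scene",
    "generate_trajectory",
    "render_frame",
    "generate_dataset",
    "default_intrinsics",
    "plane_scene",
    "sphere_scene",
]

DEPTH_NEAR_MM = 0.01
DEPTH_FAR_MM = 25.0
_SPAN = DEPTH_FAR_MM - DEPTH_NEAR_MM


# ----------------------------------------------------------------------
# Depth maps
# ----------------------------------------------------------------------

@dataclass
class DepthMap:
    """H x W depth image, either metric (mm) or normalized to [0, 1]."""

    values: np.ndarray
    mode: str = "metric"  # "metric" | "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mode not in ("metric", "normalized"):
            raise ValueError(f"unknown depth mode {self.mode!r}")

    @property
    def shape(self):
        return self.values.shape


def normalize_depth(d: DepthMap) -> DepthMap:
    """Metric mm -> normalized [0,1], 0 = 25 mm (far), 1 = 0.01 mm (near)."""
    if d.mode != "metric":
        raise ValueError("normalize_depth expects a metric DepthMap")
    v = np.clip(d.values, DEPTH_NEAR_MM, DEPTH_FAR_MM)
    return DepthMap((DEPTH_FAR_MM - v) / _SPAN, "normalized")


def denormalize_depth(d: DepthMap) -> DepthMap:
    """Normalized [0,1] -> metric mm; exact inverse of :func:`normalize_depth`."""
    if d.mode != "normalized":
        raise ValueError("denormalize_depth expects a normalized DepthMap")
    v = np.clip(d.values, 0.0, 1.0)
    return DepthMap(DEPTH_FAR_MM - v * _SPAN, "metric")


def denormalize_value(n) -> np.ndarray | float:
    """Scalar/array convenience for the same linear map."""
    return DEPTH_FAR_MM - np.clip(n, 0.0, 1.0) * _SPAN


# ----------------------------------------------------------------------
# Scene
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LightSource:
    """Point light rigidly attached to the camera (offset in camera frame)."""

    offset_from_camera: tuple[float, float, float] = (0.0, 0.0, 0.0)
    power: float = 20.0  # irradiance at 1 mm for a facing surface

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValueError("light power must be positive")


def default_lights() -> list[LightSource]:
    """Two equal point lights offset +-1 mm laterally from the camera."""
    return [
        LightSource((-1.0, 0.0, 0.0), 20.0),
        LightSource((1.0, 0.0, 0.0), 20.0),
    ]


@dataclass(frozen=True)
class AirwaySceneParams:
    """Shape parameters of the procedural lumen (all lengths mm)."""

    tube_length: float = 60.0
    mean_radius: float = 4.0
    perturbation_amplitude: float = 1.0
    perturbation_frequency: float = 2.0  # cycles along the tube
    curvature_amplitude: float = 6.0  # lateral excursion of the centerline
    n_rings: int = 48
    n_segments: int = 28
    albedo: tuple[float, float, float] = (0.85, 0.42, 0.38)  # light red

    def validate(self) -> None:
        if self.mean_radius - self.perturbation_amplitude <= 1.0:
            raise ValueError(
                "radius perturbation admits wall radii <= 1 mm "
                "(self-intersection risk): require mean_radius - amplitude > 1"
            )
        if self.perturbation_amplitude < 0:
            raise ValueError("perturbation amplitude must be >= 0")
        if self.tube_length <= 0 or self.mean_radius <= 0:
            raise ValueError("tube dimensions must be positive")


@dataclass
class AirwayScene:
    """Triangulated lumen wall plus the centerline it was extruded along."""

    mesh: trimesh.Trimesh
    albedo: np.ndarray
    params: AirwaySceneParams
    rng_seed: int
    centerline: np.ndarray  # (n, 3) points
    centerline_s: np.ndarray  # arclength parameter of each point
    frames_n1: np.ndarray  # parallel-transported normal frames
    frames_n2: np.ndarray
    closed_tube: bool = True
    # optional exact intersector (origin, dirs) -> (t, unit normals, hit);
    # used by the analytic plane/sphere validation scenes
    analytic: object = None

    # Precomputed triangle arrays for the renderer
    def __post_init__(self) -> None:
        tri = self.mesh.triangles.astype(np.float64)
        self._v0 = tri[:, 0]
        self._e1 = tri[:, 1] - tri[:, 0]
        self._e2 = tri[:, 2] - tri[:, 0]
        self._n = np.cross(self._e1, self._e2)
        norm = np.linalg.norm(self._n, axis=1, keepdims=True)
        self._n_unit = self._n / np.maximum(norm, 1e-30)
        self._centroid = tri.mean(axis=1)
        # barycentric basis: (h - v0) . U -> u, (h - v0) . V -> v
        e11 = np.einsum("ij,ij->i", self._e1, self._e1)
        e12 = np.einsum("ij,ij->i", self._e1, self._e2)
        e22 = np.einsum("ij,ij->i", self._e2, self._e2)
        det = np.maximum(e11 * e22 - e12**2, 1e-30)
        self._U = (e22[:, None] * self._e1 - e12[:, None] * self._e2) / det[:, None]
        self._V = (e11[:, None] * self._e2 - e12[:, None] * self._e1) / det[:, None]
        self._tri_radius = float(
            np.sqrt(max(e11.max(), e22.max(), 1e-30))
        )  # upper bound on triangle extent, used by the view-cone cull

    def centerline_point(self, s: float) -> np.ndarray:
        return np.array(
            [
                np.interp(s, self.centerline_s, self.centerline[:, i])
                for i in range(3)
            ]
        )

    def centerline_frame(self, s: float):
        """(tangent, n1, n2) interpolated at arclength s."""
        t = np.array(
            [np.interp(s, self.centerline_s, np.gradient(self.centerline[:, i], self.centerline_s)) for i in range(3)]
        )
        t /= np.linalg.norm(t)
        n1 = np.array(
            [np.interp(s, self.centerline_s, self.frames_n1[:, i]) for i in range(3)]
        )
        n1 -= t * (n1 @ t)
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(t, n1)
        return t, n1, n2


def _smooth_field(rng: np.random.Generator, n_terms: int = 6):
    """Random band-limited field f(s01, theta) with |f| <= 1 (s01 in [0,1])."""
    freq_s = rng.integers(1, 4, size=n_terms).astype(float)
    freq_t = rng.integers(0, 4, size=n_terms).astype(float)
    phase = rng.uniform(0.0, 2 * np.pi, size=n_terms)
    w = rng.uniform(0.3, 1.0, size=n_terms)
    w /= np.abs(w).sum()

    def f(s01, theta):
        s01 = np.asarray(s01, dtype=float)[..., None]
        theta = np.asarray(theta, dtype=float)[..., None]
        return np.sum(
            w * np.sin(2 * np.pi * freq_s * s01 + freq_t * theta + phase), axis=-1
        )

    return f


def generate_airway_scene(
    params: AirwaySceneParams | None = None, seed: int = 0
) -> AirwayScene:
    """Build the procedural curved-tube lumen, deterministic per (params, seed).

    The wall radius is ``mean_radius + amplitude * f(s, theta)`` where ``f``
    is a seeded band-limited random field bounded in [-1, 1] (a sum of
    sinusoids in arclength and azimuth with normalized weights), producing
    smooth turbinate-like constrictions.
    """
    params = params or AirwaySceneParams()
    params.validate()
    rng = np.random.default_rng(seed)
    field_f = _smooth_field(rng)
    phase_x = rng.uniform(0, 2 * np.pi)
    phase_y = rng.uniform(0, 2 * np.pi)

    n_fine = max(params.n_rings * 4, 200)
    s = np.linspace(0.0, params.tube_length, n_fine)
    u = s / params.tube_length
    cl = np.stack(
        [
            params.curvature_amplitude * np.sin(1.5 * np.pi * u + phase_x) * u,
            0.6 * params.curvature_amplitude * np.sin(1.0 * np.pi * u + phase_y) * u,
            s,
        ],
        axis=1,
    )
    # Parallel-transport an orthonormal frame along the centerline so rings
    # do not twist.
    tangents = np.gradient(cl, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n1 = np.zeros_like(tangents)
    v = np.array([1.0, 0.0, 0.0])
    v = v - tangents[0] * (v @ tangents[0])
    n1[0] = v / np.linalg.norm(v)
    for i in range(1, n_fine):
        v = n1[i - 1] - tangents[i] * (n1[i - 1] @ tangents[i])
        n1[i] = v / np.linalg.norm(v)
    n2 = np.cross(tangents, n1)

    ring_idx = np.linspace(0, n_fine - 1, params.n_rings).round().astype(int)
    theta = np.linspace(0.0, 2 * np.pi, params.n_segments, endpoint=False)
    verts = []
    for i in ring_idx:
        r = params.mean_radius + params.perturbation_amplitude * field_f(
            np.full_like(theta, u[i]), theta
        )
        ring = (
            cl[i]
            + np.outer(r * np.cos(theta), n1[i])
            + np.outer(r * np.sin(theta), n2[i])
        )
        verts.append(ring)
    verts = np.concatenate(verts, axis=0)

    faces = []
    ns = params.n_segments
    for i in range(params.n_rings - 1):
        for k in range(ns):
            a = i * ns + k
            b = i * ns + (k + 1) % ns
            c = (i + 1) * ns + k
            d = (i + 1) * ns + (k + 1) % ns
            # wind so triangle normals point inward (toward the centerline)
            faces.append([a, c, b])
            faces.append([b, c, d])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    return AirwayScene(
        mesh=mesh,
        albedo=np.asarray(params.albedo, dtype=float),
        params=params,
        rng_seed=seed,
        centerline=cl,
        centerline_s=s,
        frames_n1=n1,
        frames_n2=n2,
        closed_tube=True,
    )


def plane_scene(z_mm: float, half_extent: float = 100.0) -> AirwayScene:
    """Validation scene: a plane z = z_mm, intersected in closed form."""
    h = half_extent
    verts = np.array(
        [[-h, -h, z_mm], [h, -h, z_mm], [h, h, z_mm], [-h, h, z_mm]]
    )
    faces = np.array([[0, 2, 1], [0, 3, 2]])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    scene = _adhoc_scene(mesh)

    def cast(origin, dirs):
        dz = dirs[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (z_mm - origin[2]) / dz
        p = origin[None, :] + t[:, None] * dirs
        hit = (
            (np.abs(dz) > 1e-15)
            & (t > 1e-9)
            & (np.abs(p[:, 0]) <= h)
            & (np.abs(p[:, 1]) <= h)
        )
        t = np.where(hit, t, np.inf)
        normals = np.tile(np.array([0.0, 0.0, -1.0]), (len(dirs), 1))
        return t, normals, hit

    scene.analytic = cast
    return scene


def sphere_scene(center, radius: float) -> AirwayScene:
    """Validation scene: a sphere, intersected in closed form."""
    center = np.asarray(center, dtype=float)
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=radius)
    mesh.apply_translation(center)
    scene = _adhoc_scene(mesh)

    def cast(origin, dirs):
        oc = origin - center
        a = np.einsum("ij,ij->i", dirs, dirs)
        b = 2.0 * dirs @ oc
        c0 = float(oc @ oc) - radius**2
        disc = b * b - 4 * a * c0
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1 = (-b - sq) / (2 * a)
        t2 = (-b + sq) / (2 * a)
        t = np.where(t1 > 1e-9, t1, t2)
        hit = ok & (t > 1e-9)
        t = np.where(hit, t, np.inf)
        t_safe = np.where(hit, t, 0.0)
        p = origin[None, :] + t_safe[:, None] * dirs
        normals = np.zeros_like(dirs)
        normals[hit] = (p[hit] - center) / radius
        return t, normals, hit

    scene.analytic = cast
    return scene


def _adhoc_scene(mesh: trimesh.Trimesh) -> AirwayScene:
    z = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    return AirwayScene(
        mesh=mesh,
        albedo=np.array([1.0, 1.0, 1.0]),
        params=AirwaySceneParams(),
        rng_seed=0,
        centerline=z,
        centerline_s=np.array([0.0, 1.0]),
        frames_n1=np.array([[1.0, 0.0, 0.0]] * 2),
        frames_n2=np.array([[0.0, 1.0, 0.0]] * 2),
        closed_tube=False,
    )


# ----------------------------------------------------------------------
# Trajectory
# ----------------------------------------------------------------------

@dataclass
class Trajectory:
    """Timestamped camera poses (world<-camera)."""

    poses: list[RigidTransform]
    timestamps: np.ndarray
    arclengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)


def generate_trajectory(
    scene: AirwayScene,
    n_frames: int,
    speed: float = 3.0,
    sample_rate: float = 50.0,
    seed: int = 0,
    mode: str = "forward",
    jitter_translation: float = 0.15,
    jitter_rotation: float = 0.03,
    margin: float = 6.0,
) -> Trajectory:
    """Camera path along the lumen centerline with seeded jitter.

    ``mode='forward'`` advances monotonically; ``'forward_backward'``
    oscillates between the margins (the stability-protocol motion).  Per-step
    centerline displacement is ``speed / sample_rate``.  Jitter is smooth
    (random low-frequency sinusoids), small enough to stay off the wall.
    """
    if not speed > 0:
        raise ValueError("speed must be positive")
    if mode == "forward_backward" and speed >= 3.0 + 1e-12:
        import logging

        logging.getLogger(__name__).warning(
            "stability-protocol trajectories should keep speed below 3 mm/s "
            "(requested %.3g mm/s)",
            speed,
        )
    rng = np.random.default_rng(seed)
    step = speed / sample_rate
    L = scene.centerline_s[-1]
    lo, hi = margin, L - margin
    if hi <= lo:
        raise ValueError("tube too short for the requested margin")
    t = np.arange(n_frames) / sample_rate
    raw = lo + step * np.arange(n_frames)
    if mode == "forward":
        s_path = np.minimum(raw, hi)
    elif mode == "forward_backward":
        span = hi - lo
        phase = np.mod(step * np.arange(n_frames), 2 * span)
        s_path = lo + np.where(phase <= span, phase, 2 * span - phase)
    else:
        raise ValueError(f"unknown trajectory mode {mode!r}")

    # Smooth lateral/angular jitter as sums of low-frequency sinusoids.
    def smooth_jitter(amp: float) -> np.ndarray:
        if amp == 0.0 or n_frames < 2:
            return np.zeros(n_frames)
        f = rng.uniform(0.05, 0.3, size=3)
        ph = rng.uniform(0, 2 * np.pi, size=3)
        w = rng.uniform(0.3, 1.0, size=3)
        w /= np.abs(w).sum()
        return amp * np.sum(
            w[:, None] * np.sin(2 * np.pi * f[:, None] * t[None, :] + ph[:, None]),
            axis=0,
        )

    j1, j2 = smooth_jitter(jitter_translation), smooth_jitter(jitter_translation)
    a1, a2 = smooth_jitter(jitter_rotation), smooth_jitter(jitter_rotation)

    poses = []
    for i, s in enumerate(s_path):
        tang, n1, n2 = scene.centerline_frame(s)
        origin = scene.centerline_point(s) + j1[i] * n1 + j2[i] * n2
        z_axis = tang + a1[i] * n1 + a2[i] * n2
        z_axis /= np.linalg.norm(z_axis)
        x_axis = n1 - z_axis * (n1 @ z_axis)
        x_axis /= np.linalg.norm(x_axis)
        y_axis = np.cross(z_axis, x_axis)
        R = np.stack([x_axis, y_axis, z_axis], axis=1)
        poses.append(RigidTransform(R, origin, "camera", "world"))
    return Trajectory(poses=poses, timestamps=t, arclengths=s_path)


# ----------------------------------------------------------------------
# Renderer
# ----------------------------------------------------------------------

@dataclass
class RenderedFrame:
    rgb: np.ndarray  # H x W x 3 in [0, 1]
    depth: DepthMap  # metric mm, z-depth
    pose: RigidTransform
    frame_index: int = 0


def _cull_triangles(
    scene: AirwayScene,
    origin: np.ndarray,
    Rz: np.ndarray,
    cos_half_angle: float | None = None,
):
    """Indices of triangles that can matter for this camera."""
    rel = scene._centroid - origin
    d = np.linalg.norm(rel, axis=1)
    keep = d < DEPTH_FAR_MM * 1.3
    # drop triangles entirely behind the camera
    keep &= rel @ Rz > -2.0 * scene.params.mean_radius
    if cos_half_angle is not None:
        # view-cone cull with a margin of one triangle circumradius
        margin = getattr(scene, "_tri_radius", 2.0)
        keep &= rel @ Rz >= cos_half_angle * d - 2.0 * margin
    if scene.closed_tube:
        # inside a tube only inward faces pointing back at the camera matter
        keep &= np.einsum("ij,ij->i", scene._n_unit, rel) < 0
    return np.nonzero(keep)[0]


def scene_cast(
    scene: AirwayScene,
    origin: np.ndarray,
    dirs_world: np.ndarray,
    Rz: np.ndarray | None = None,
    cos_half_angle: float | None = None,
):
    """First-hit query for rays from a common origin.

    Returns (t, unit normals at the hits, hit mask).  Uses the scene's exact
    intersector when present, otherwise the culled triangle-mesh caster.
    """
    if scene.analytic is not None:
        return scene.analytic(origin, dirs_world)
    if Rz is None:
        Rz = np.array([0.0, 0.0, 1.0])
    tri_idx = _cull_triangles(scene, origin, Rz, cos_half_angle)
    n_rays = len(dirs_world)
    if len(tri_idx) == 0:
        return (
            np.full(n_rays, np.inf),
            np.zeros((n_rays, 3)),
            np.zeros(n_rays, dtype=bool),
        )
    t, i_hit, hit = cast_rays(scene, origin, dirs_world, tri_idx)
    normals = np.zeros((n_rays, 3))
    normals[hit] = scene._n_unit[i_hit[hit]]
    return t, normals, hit


def cast_rays(
    scene: AirwayScene,
    origin: np.ndarray,
    dirs_world: np.ndarray,
    tri_idx: np.ndarray | None = None,
    chunk: int = 2048,
):
    """Nearest-hit Moller-Trumbore for rays from a common origin.

    Returns (t, tri_index, hit_mask); ``t`` is the ray parameter such that
    the hit point is ``origin + t * dir`` (np.inf on miss).
    """
    if tri_idx is None:
        tri_idx = np.arange(len(scene._v0))
    v0 = scene._v0[tri_idx]
    n = scene._n[tri_idx]
    U = scene._U[tri_idx]
    V = scene._V[tri_idx]
    # plane hit: t = n.(v0 - o) / n.d ; barycentrics from precomputed basis:
    # u = (o - v0).U + t * d.U  (and likewise v), all BLAS matmuls
    w0 = v0 - origin  # (m, 3)
    a = np.einsum("mk,mk->m", n, w0)  # n.(v0 - o)
    c1 = -np.einsum("mk,mk->m", w0, U)
    c2 = -np.einsum("mk,mk->m", w0, V)
    n_rays = len(dirs_world)
    t_best = np.full(n_rays, np.inf)
    i_best = np.full(n_rays, -1, dtype=np.int64)
    for lo in range(0, n_rays, chunk):
        d = dirs_world[lo : lo + chunk]
        nd = d @ n.T  # (r, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = a[None, :] / nd
        u = c1[None, :] + t * (d @ U.T)
        v = c2[None, :] + t * (d @ V.T)
        ok = (
            (np.abs(nd) > 1e-14)
            & (t > 1e-6)
            & (u >= -1e-9)
            & (v >= -1e-9)
            & (u + v <= 1.0 + 1e-9)
        )
        t = np.where(ok, t, np.inf)
        j = np.argmin(t, axis=1)
        tmin = t[np.arange(len(d)), j]
        sl = slice(lo, lo + len(d))
        t_best[sl] = tmin
        i_best[sl] = np.where(np.isfinite(tmin), tri_idx[j], -1)
    return t_best, i_best, np.isfinite(t_best)


def render_frame(
    scene: AirwayScene,
    pose: RigidTransform,
    K: CameraIntrinsics,
    lights: list[LightSource] | None = None,
    frame_index: int = 0,
) -> RenderedFrame:
    """Ray-cast one frame: Lambertian shading under co-moving point lights.

    Per-pixel primary ray through the pixel center; radiance is
    ``albedo * sum_l power_l * max(0, n.l) / r_l^2`` (no shadows or bounces),
    clamped to [0, 1].  Depth is the camera-frame z of the hit point; miss
    pixels get the far clamp (25 mm) and black RGB.
    """
    lights = default_lights() if lights is None else lights
    H, W = K.height, K.width
    R, origin = pose.rotation, pose.translation
    uu, vv = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    dirs_cam = np.stack(
        [(uu - K.cx) / K.fx, (vv - K.cy) / K.fy, np.ones_like(uu)], axis=-1
    ).reshape(-1, 3)
    dirs_world = dirs_cam @ R.T  # z-component of dirs_cam is 1 -> t == z-depth

    # widest ray angle (a frame corner) bounds the view cone for culling
    corner = max(
        np.linalg.norm([(u - K.cx) / K.fx, (v - K.cy) / K.fy, 1.0])
        for u in (0, W - 1)
        for v in (0, H - 1)
    )
    t, normals, hit = scene_cast(
        scene, origin, dirs_world, R[:, 2], cos_half_angle=1.0 / corner
    )

    depth = np.where(hit, t, DEPTH_FAR_MM).reshape(H, W)
    depth = np.clip(depth, DEPTH_NEAR_MM, DEPTH_FAR_MM)

    rgb = np.zeros((len(dirs_world), 3))
    if hit.any():
        hp = origin + dirs_world[hit] * t[hit, None]
        n = normals[hit]
        # orient the shading normal toward the camera ray
        facing = np.einsum("ij,ij->i", n, dirs_world[hit])
        n = np.where(facing[:, None] > 0, -n, n)
        shade = np.zeros(len(hp))
        for light in lights:
            lp = origin + R @ np.asarray(light.offset_from_camera, dtype=float)
            lv = lp - hp
            r2 = np.einsum("ij,ij->i", lv, lv)
            lv_unit = lv / np.sqrt(r2)[:, None]
            cosi = np.maximum(0.0, np.einsum("ij,ij->i", n, lv_unit))
            shade += light.power * cosi / np.maximum(r2, 1e-12)
        rgb[hit] = np.clip(shade[:, None] * scene.albedo[None, :], 0.0, 1.0)
    return RenderedFrame(
        rgb.reshape(H, W, 3), DepthMap(depth, "metric"), pose, frame_index
    )


# ----------------------------------------------------------------------
# Dataset generation
# ----------------------------------------------------------------------

def default_intrinsics(width: int = 64, height: int = 64, fov_deg: float = 80.0) -> CameraIntrinsics:
    """Wide-angle endoscope-like pinhole intrinsics for a given resolution."""
    f = (width / 2.0) / np.tan(np.radians(fov_deg) / 2.0)
    return CameraIntrinsics(
        fx=f, fy=f, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
        width=width, height=height,
    )


def generate_dataset(
    scene: AirwayScene,
    trajectory: Trajectory,
    K: CameraIntrinsics,
    lights: list[LightSource] | None = None,
    out_dir: str | Path = "dataset",
    n: int | None = None,
) -> dict:
    """Render frames along a trajectory and write an on-disk dataset.

    Writes 8-bit RGB PNGs, 16-bit normalized-depth PNGs, a pose CSV, an
    intrinsics JSON, and a manifest JSON; byte-identical per (scene seed,
    trajectory, intrinsics).
    """
    from .io import write_depth_png, write_rgb_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(trajectory) if n is None else min(n, len(trajectory))
    entries = []
    for i in range(n):
        frame = render_frame(scene, trajectory.poses[i], K, lights, i)
        rgb_name = f"rgb_{i:05d}.png"
        depth_name = f"depth_{i:05d}.png"
        write_rgb_png(out / rgb_name, frame.rgb)
        write_depth_png(out / depth_name, normalize_depth(frame.depth))
        entries.append(
            {
                "frame_index": i,
                "rgb": rgb_name,
                "depth": depth_name,
                "timestamp": float(trajectory.timestamps[i]),
            }
        )
    save_poses_csv(out / "poses.csv", trajectory.poses[:n])
    save_intrinsics(out / "intrinsics.json", K, DistortionCoefficients())
    config = {
        "scene_params": asdict(scene.params),
        "scene_seed": scene.rng_seed,
        "n_frames": n,
        "depth_near_mm": DEPTH_NEAR_MM,
        "depth_far_mm": DEPTH_FAR_MM,
    }
    manifest = {
        "n": n,
        "entries": entries,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
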