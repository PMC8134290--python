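import numpy as np
import pytest

from endo3d import simulator as sim
from endo3d.geometry import CameraIntrinsics, RigidTransform


@pytest.fixture(scope="session")
def K64() -> CameraIntrinsics:
    """64x64 endoscope-like intrinsics with an integer principal point."""
    return CameraIntrinsics(fx=40.0, fy=40.0, cx=32.0, cy=32.0, width=64, height=64)


@pytest.fixture(scope="session")
def airway_scene():
    return sim.generate_airway_scene(seed=1)


@pytest.fixture(scope="session")
def short_trajectory(airway_scene):
    return sim.generate_trajectory(airway_scene, 8, speed=2.5, sample_rate=50, seed=2)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, airway_scene, short_trajectory, K64):
    """8 rendered frames with depth PNGs, poses and manifest on disk."""
    out = tmp_path_factory.mktemp("dataset")
    sim.generate_dataset(airway_scene, short_trajectory, K64, out_dir=out)
    return out


def point_mesh_distance(mesh, points: np.ndarray) -> np.ndarray:
    """Exact distance from each query point to the nearest mesh triangle."""
    import trimesh.triangles as tt

    tris = mesh.triangles
    out = []
    for p in np.atleast_2d(points):
        closest = tt.closest_point(tris, np.tile(p, (len(tris), 1)))
        out.append(np.linalg.norm(closest - p, axis=1).min())
    return np.array(out)


def random_rigid(rng: np.random.Generator, source="source", target="target",
                 t_scale: float = 10.0) -> RigidTransform:
    """Uniformly random rotation (QR of a Gaussian) plus Gaussian translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return RigidTransform(Q, rng.normal(scale=t_scale, size=3), source, target)
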