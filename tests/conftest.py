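import numpy as np
import pytest
import trimesh

from mandair.mesh_core import Plane, SurfaceMesh
from mandair import phantom as ph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def icosphere10():
    """Icosphere of radius 10 mm, subdivision level 4."""
    tm = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return SurfaceMesh.from_trimesh(tm, "icosphere10")


@pytest.fixture(scope="session")
def cylinder_r5():
    """Closed tube, radius 5 mm, z in [-10, 10], 128 circumferential segments."""
    z = np.linspace(-10.25, 10.25, 42)
    return ph.tube_mesh(z, np.full_like(z, 5.0), segments=128, name="cyl5")


@pytest.fixture
def z_plane():
    return Plane([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])


def random_rigid(rng, max_angle_deg=180.0, max_trans=50.0):
    from scipy.spatial.transform import Rotation

    from mandair.registration import RigidTransform

    angle = rng.uniform(-max_angle_deg, max_angle_deg, 3)
    r = Rotation.from_euler("XYZ", angle, degrees=True).as_matrix()
    t = rng.uniform(-max_trans, max_trans, 3)
    return RigidTransform(r, t)


@pytest.fixture
def ascii_cube_stl(tmp_path):
    """Unit cube as ASCII STL (12 facets, duplicated per-facet vertices)."""
    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    path = tmp_path / "cube.stl"
    path.write_bytes(trimesh.exchange.stl.export_stl_ascii(tm).encode())
    return path
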