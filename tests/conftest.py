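"""Shared fixtures: sphere meshes, distance fields, cameras and grids."""

import numpy as np
import pytest
import trimesh

from usnav.markers import CircleGridModel
from usnav.phantom import default_camera
from usnav.volume import SignedDistanceField, SurfaceMesh, build_sdf


def icosphere_mesh(radius: float = 10.0, subdivisions: int = 3,
                   center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    tm.apply_translation(center)
    return SurfaceMesh(vertices=np.asarray(tm.vertices),
                       triangles=np.asarray(tm.faces))


@pytest.fixture(scope="session")
def sphere_mesh() -> SurfaceMesh:
    """Radius-10 mm sphere centred at the origin (aid frame)."""
    return icosphere_mesh()


@pytest.fixture(scope="session")
def coarse_sphere_mesh() -> SurfaceMesh:
    """A coarse sphere cheap enough for brute-force distance oracles."""
    return icosphere_mesh(subdivisions=2)


@pytest.fixture(scope="session")
def sphere_sdf(sphere_mesh) -> SignedDistanceField:
    """1 mm signed distance field of the radius-10 sphere, 10 mm margin."""
    return build_sdf(sphere_mesh, voxel=1.0, margin=10.0)


@pytest.fixture(scope="session")
def fine_sphere_sdf() -> SignedDistanceField:
    """High-resolution field for ray-hit accuracy checks: a finely faceted
    radius-10 sphere (chord sag ~0.01 mm) at 0.25 mm voxels, trimmed margin."""
    mesh = icosphere_mesh(subdivisions=4)
    return build_sdf(mesh, voxel=0.25, margin=3.0)


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def grid():
    return CircleGridModel()
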