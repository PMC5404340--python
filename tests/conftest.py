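"""Shared fixtures: all geometry is generated programmatically at test time."""

import numpy as np
import pytest
import trimesh

from simplexssm.mesh import dual_simplex_from_triangles
from simplexssm.pipeline import PipelineConfig, energy_volume_for
from simplexssm.synthetic import make_ellipsoid_volume


@pytest.fixture(scope="session")
def icosphere_dual():
    """Dual simplex mesh of a subdivided icosphere (radius 5 mm, 1280 faces)."""
    return dual_simplex_from_triangles(
        trimesh.creation.icosphere(subdivisions=3, radius=5.0))


@pytest.fixture(scope="session")
def coarse_sphere_dual():
    """Dual simplex mesh of a 320-face icosphere (radius 10 mm)."""
    return dual_simplex_from_triangles(
        trimesh.creation.icosphere(subdivisions=2, radius=10.0))


@pytest.fixture(scope="session")
def sphere_volume():
    """Digitized sphere, radius 10 mm, 1 mm spacing, 32^3 grid."""
    return make_ellipsoid_volume((10.0, 10.0, 10.0), dims=(32, 32, 32))


@pytest.fixture(scope="session")
def sphere_energy(sphere_volume):
    """VFC energy volume of the digitized sphere (kernel radius 6)."""
    return energy_volume_for(sphere_volume, PipelineConfig(vfc_R=6))


@pytest.fixture(scope="session")
def rank1_family():
    """Shapes exactly on a 1-mode linear family: x = base + b*phi.

    The mode field has zero net translation per landmark (as deviations of
    jointly aligned shapes always do), so in-span reconstructions are exact.
    Returns (shapes (5, 3N), base, phi, b_values).
    """
    rng = np.random.default_rng(42)
    N = 40
    base = rng.normal(size=(N, 3)) * 10
    base -= base.mean(axis=0)
    phi = rng.normal(size=(N, 3))
    phi -= phi.mean(axis=0)  # no net translation
    phi = phi.ravel()
    phi /= np.linalg.norm(phi)
    b = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    shapes = base.ravel() + b[:, None] * phi
    return shapes, base.ravel(), phi, b
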