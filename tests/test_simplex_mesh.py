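"""2-simplex mesh structure and local geometry."""

import numpy as np
import pytest
import trimesh

from simplexssm.errors import DegenerateGeometryError, NonManifoldMeshError
from simplexssm.mesh import (
    SimplexMesh,
    dual_simplex_from_triangles,
    load_simplex_mesh,
    mesh_geometry,
    reconstruct_position,
    save_simplex_mesh,
    simplex_height,
    vertex_geometry,
)


def _tetrahedron():
    return trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]], process=False)


# --- independent geometric oracle -----------------------------------------

def _oracle_circumcircle(N):
    """Circumcircle of 3 points by explicit bisector solve."""
    a, b, c = N
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    ab, ac = b - a, c - a
    M = np.array([[ab @ ab, ab @ ac], [ab @ ac, ac @ ac]])
    x, y = np.linalg.solve(M, 0.5 * np.array([ab @ ab, ac @ ac]))
    C = a + x * ab + y * ac
    return C, np.linalg.norm(C - a), n


def _oracle_circumsphere(P, N):
    """Circumsphere of 4 points by the explicit 3x3 linear solve."""
    pts = np.vstack([P, N])
    A = 2.0 * (pts[1:] - pts[0])
    rhs = np.einsum("ij,ij->i", pts[1:], pts[1:]) - pts[0] @ pts[0]
    O = np.linalg.solve(A, rhs)
    return O, np.linalg.norm(O - pts[0])


# --- dual construction -----------------------------------------------------

@pytest.mark.parametrize("tri_factory, n_dual_vertices, n_edges", [
    (_tetrahedron, 4, 6),                                        # self-dual
    (lambda: trimesh.creation.icosphere(subdivisions=0), 20, 30),
])
def test_dual_counts(tri_factory, n_dual_vertices, n_edges):
    sm = dual_simplex_from_triangles(tri_factory())
    assert sm.n_vertices == n_dual_vertices
    assert len(sm.edges()) == n_edges
    assert sm.euler_characteristic() == 2
    sm.validate()


def test_dual_of_subdivided_sphere_stays_near_sphere():
    tri = trimesh.creation.icosphere(subdivisions=2)  # 320 faces, unit radius
    sm = dual_simplex_from_triangles(tri)
    assert sm.n_vertices == 320
    assert np.all([len(set(row)) == 3 for row in sm.neighbors])
    edge_len = np.linalg.norm(
        sm.vertices[sm.edges()[:, 0]] - sm.vertices[sm.edges()[:, 1]], axis=1)
    radii = np.linalg.norm(sm.vertices, axis=1)
    assert np.all(np.abs(radii - 1.0) < edge_len.max())


def test_dual_neighbor_symmetry_and_outward_normals(icosphere_dual):
    icosphere_dual.validate()
    g = mesh_geometry(icosphere_dual)
    # outward orientation on a sphere: normal . radial direction > 0
    radial = icosphere_dual.vertices / np.linalg.norm(
        icosphere_dual.vertices, axis=1, keepdims=True)
    assert np.all(np.einsum("ij,ij->i", g["n"], radial) > 0)


def test_open_mesh_rejected_with_edge_diagnostic():
    tri = _tetrahedron()
    open_tri = trimesh.Trimesh(vertices=tri.vertices, faces=tri.faces[:3],
                               process=False)
    with pytest.raises(NonManifoldMeshError, match="edge"):
        dual_simplex_from_triangles(open_tri)


# --- vertex geometry --------------------------------------------------------

def _flat_patch():
    """Central vertex 0 in the plane of its equilateral neighbors; the
    neighbors themselves are also flat, so the reference angle is 0."""
    ang = np.arange(3) * 2 * np.pi / 3
    inner = np.stack([np.cos(ang), np.sin(ang), np.zeros(3)], axis=1)
    ang2 = np.arange(6) * np.pi / 3 + 0.1
    outer = 2.5 * np.stack([np.cos(ang2), np.sin(ang2), np.zeros(6)], axis=1)
    verts = np.vstack([[[0, 0, 0]], inner, outer])
    neighbors = np.array([
        [1, 2, 3],
        [0, 4, 5], [0, 6, 7], [0, 8, 9],
        [5, 9, 1], [4, 6, 1], [5, 7, 2], [6, 8, 2], [7, 9, 3], [8, 4, 3],
    ])
    return SimplexMesh(verts, neighbors)


def test_vertex_in_plane_of_equilateral_neighbors():
    geom = vertex_geometry(_flat_patch(), 0)
    assert np.allclose(geom.eps, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)
    assert geom.phi == pytest.approx(0.0, abs=1e-12)
    assert geom.L == pytest.approx(0.0, abs=1e-12)
    assert geom.H == pytest.approx(0.0, abs=1e-12)


def test_geometry_against_explicit_circumsphere_oracle():
    """All reported quantities agree with an independent construction."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        N = rng.normal(size=(3, 3)) * 3
        C, r, n = _oracle_circumcircle(N)
        # place P with the projection inside the circumcircle (d < r)
        e = rng.dirichlet([2, 2, 2])
        F = e @ N
        if np.linalg.norm(F - C) >= 0.95 * r:
            continue
        P = F + rng.uniform(-2, 2) * n
        mesh = SimplexMesh(np.vstack([P, N]),
                           np.array([[1, 2, 3]] * 4))
        geom = vertex_geometry(mesh, 0)
        assert geom.eps.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(geom.eps, e, atol=1e-9)
        assert np.allclose(geom.C, C, atol=1e-9)
        assert geom.r == pytest.approx(r, abs=1e-9)
        assert geom.d == pytest.approx(np.linalg.norm(F - C), abs=1e-9)
        # circumsphere: equidistant from all four points
        O, R = _oracle_circumsphere(P, N)
        assert np.allclose(geom.O, O, atol=1e-6)
        assert geom.R == pytest.approx(R, abs=1e-6)
        assert abs(np.cos(geom.phi)) == pytest.approx(
            np.linalg.norm(C - O) / R, abs=1e-9)
        assert geom.H == pytest.approx(np.sin(geom.phi) / r, abs=1e-12)
        assert geom.L == pytest.approx((P - F) @ n, abs=1e-9)


def test_mean_curvature_of_fine_sphere_dual():
    rho = 5.0
    sm = dual_simplex_from_triangles(
        trimesh.creation.icosphere(subdivisions=4, radius=rho))
    H = mesh_geometry(sm)["H"]
    err = np.abs(H - 1.0 / rho)
    # the duals around the 12 icosahedral poles feel the lattice
    # irregularity; the analytic limit holds for the regular bulk
    assert np.median(err) < 0.01 / rho
    assert np.mean(err < 0.05 / rho) > 0.8
    assert err.max() < 0.15 / rho


def test_collinear_neighbors_rejected():
    verts = np.array([[0.0, 0, 1], [0, 0, 0], [1, 0, 0], [2, 0, 0]])
    mesh = SimplexMesh(verts, np.array([[1, 2, 3]] * 4))
    with pytest.raises(DegenerateGeometryError):
        vertex_geometry(mesh, 0)


def test_height_formula_at_right_angle():
    # |phi| = pi/2 is the circumcircle-plane limit: L = +-sqrt(r^2 - d^2)
    assert simplex_height(2.0, 1.0, np.pi / 2) == pytest.approx(np.sqrt(3.0))
    assert simplex_height(2.0, 1.0, -np.pi / 2) == pytest.approx(-np.sqrt(3.0))


# --- reconstruction round trip ---------------------------------------------

def test_round_trip_on_fixture_meshes(icosphere_dual, coarse_sphere_dual):
    """>= 100 random vertices: metric parameters + simplex angle reproduce
    the vertex position through the height formula to < 1e-6 mm."""
    rng = np.random.default_rng(0)
    checked = 0
    for mesh in (icosphere_dual, coarse_sphere_dual):
        idx = rng.choice(mesh.n_vertices, size=60, replace=False)
        for i in idx:
            geom = vertex_geometry(mesh, int(i))
            p = reconstruct_position(geom, mesh.vertices[mesh.neighbors[i]])
            assert np.linalg.norm(p - mesh.vertices[i]) < 1e-6
            checked += 1
    assert checked >= 100


def test_round_trip_in_plane_when_flat():
    mesh = _flat_patch()
    geom = vertex_geometry(mesh, 0)
    p = reconstruct_position(geom, mesh.vertices[mesh.neighbors[0]])
    assert abs(p[2]) < 1e-12  # stays in the neighbor plane


def test_orientation_flip_negates_angle_and_height(coarse_sphere_dual):
    mesh = coarse_sphere_dual
    flipped = mesh.copy()
    flipped.neighbors = flipped.neighbors[:, [0, 2, 1]]
    for i in (0, 17, 101):
        g = vertex_geometry(mesh, i)
        gf = vertex_geometry(flipped, i)
        assert gf.phi == pytest.approx(-g.phi, abs=1e-12)
        assert gf.L == pytest.approx(-g.L, abs=1e-12)
        assert np.allclose(gf.n, -g.n, atol=1e-12)
        p = reconstruct_position(gf, flipped.vertices[flipped.neighbors[i]])
        assert np.linalg.norm(p - mesh.vertices[i]) < 1e-9


def test_metric_parameters_sum_to_one_everywhere(icosphere_dual):
    eps = mesh_geometry(icosphere_dual)["eps"]
    assert np.max(np.abs(eps.sum(axis=1) - 1.0)) < 1e-12


# --- serialization ----------------------------------------------------------

def test_ply_json_round_trip(tmp_path, coarse_sphere_dual):
    path = tmp_path / "mesh.ply"
    save_simplex_mesh(coarse_sphere_dual, path)
    back = load_simplex_mesh(path)
    assert np.array_equal(back.vertices, coarse_sphere_dual.vertices)
    assert np.array_equal(back.neighbors, coarse_sphere_dual.neighbors)
    assert back.faces == [list(f) for f in coarse_sphere_dual.faces]
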