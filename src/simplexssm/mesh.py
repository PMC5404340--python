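"""2-simplex meshes and their local geometry.

A 2-simplex mesh is a closed polygonal surface in which every vertex has
exactly three neighbors; it is the topological dual of a triangle mesh.  The
local geometry of a vertex ``P`` with neighbors ``(N1, N2, N3)`` is described
by

* the *metric parameters* ``(eps1, eps2, eps3)`` — barycentric coordinates of
  the orthogonal projection ``F`` of ``P`` onto the neighbor plane (they sum
  to one and control tangential placement),
* the *simplex angle* ``phi`` in ``[-pi, pi]`` — a signed angle defined
  through the circumscribed circle (center ``C``, radius ``r``) of the
  neighbor triangle and the circumscribed sphere (center ``O``, radius ``R``)
  of the tetrahedron ``(P, N1, N2, N3)``; it controls the local mean
  curvature ``H = sin(phi) / r``,
* the *height* ``L(r, d, phi)`` of ``P`` above the neighbor plane, where
  ``d = ||F - C||``.

Together they reconstruct the vertex exactly:
``P = eps1*N1 + eps2*N2 + eps3*N3 + L(r, d, phi) * n``.

Sign conventions: the tangent-plane normal is
``n = normalize((N2 - N1) x (N3 - N1))`` for the stored neighbor order, which
is fixed at construction so that ``n`` points outward.  ``phi`` carries the
sign of the elevation ``(P - F) . n``; reversing the neighbor order flips
``n``, ``phi`` and ``L`` together, leaving the reconstruction unchanged.

The height parameterization is valid while ``F`` projects inside the
circumcircle (``d < r``), which holds for the well-shaped configurations a
deforming mesh visits; outside that regime the formula returns ``nan`` and
callers treat the configuration as degenerate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import DegenerateGeometryError, NonManifoldMeshError

__all__ = [
    "SimplexMesh",
    "VertexGeometry",
    "dual_simplex_from_triangles",
    "vertex_geometry",
    "reconstruct_position",
    "mesh_geometry",
    "simplex_height",
    "save_simplex_mesh",
    "load_simplex_mesh",
]


@dataclass
class SimplexMesh:
    """Closed 2-simplex surface mesh.

    Parameters
    ----------
    vertices
        ``(V, 3)`` float array of vertex positions in mm.
    neighbors
        ``(V, 3)`` int array; row ``i`` holds the ordered neighbor triple of
        vertex ``i``.  The order fixes the normal orientation.
    faces
        Polygonal dual faces (lists of vertex indices), kept for rendering,
        area computation and Euler-characteristic checks only.
    """

    vertices: np.ndarray
    neighbors: np.ndarray
    faces: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.neighbors.shape != (len(self.vertices), 3):
            raise ValueError("neighbors must be (V, 3)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) sorted-index array."""
        i = np.repeat(np.arange(self.n_vertices), 3)
        j = self.neighbors.ravel()
        e = np.sort(np.stack([i, j], axis=1), axis=1)
        return np.unique(e, axis=0)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        V = self.n_vertices
        nb = self.neighbors
        if nb.min() < 0 or nb.max() >= V:
            raise ValueError("neighbor index out of range")
        for i in range(V):
            if len(set(nb[i])) != 3 or i in nb[i]:
                raise ValueError(f"vertex {i} does not have 3 distinct neighbors")
        # symmetry: i in neighbors[j] for every j in neighbors[i]
        neighbor_sets = [set(row) for row in nb]
        for i in range(V):
            for j in nb[i]:
                if i not in neighbor_sets[j]:
                    raise ValueError(f"neighbor relation not symmetric at ({i}, {j})")

    def euler_characteristic(self) -> int:
        """V - E + F using the stored dual faces."""
        return self.n_vertices - len(self.edges()) + len(self.faces)

    def copy(self) -> "SimplexMesh":
        return SimplexMesh(self.vertices.copy(), self.neighbors.copy(),
                           [list(f) for f in self.faces])


@dataclass
class VertexGeometry:
    """Local simplex geometry of one vertex (all lengths in mm)."""

    eps: np.ndarray          # (3,) metric parameters, sum to 1
    F: np.ndarray            # orthogonal projection onto the neighbor plane
    n: np.ndarray            # unit tangent-plane normal
    C: np.ndarray            # circumcircle center of the neighbor triangle
    r: float                 # circumcircle radius
    O: np.ndarray            # circumsphere center of the tetrahedron (nan if flat)
    R: float                 # circumsphere radius (inf if flat)
    d: float                 # ||F - C||
    phi: float               # simplex angle in [-pi, pi]
    L: float                 # height of the vertex above the neighbor plane
    H: float                 # mean curvature sin(phi) / r


def _triangle_frame(N1: np.ndarray, N2: np.ndarray, N3: np.ndarray):
    """Vectorized circumcircle and oriented normal of neighbor triangles.

    All inputs ``(..., 3)``.  Returns ``(C, r, n, ab, ac)``; raises on
    collinear neighbors.
    """
    ab = N2 - N1
    ac = N3 - N1
    n = np.cross(ab, ac)
    nn = np.linalg.norm(n, axis=-1)
    scale = np.maximum(np.linalg.norm(ab, axis=-1) * np.linalg.norm(ac, axis=-1), 1e-300)
    bad = nn < 1e-12 * scale
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise DegenerateGeometryError(
            f"collinear neighbors (degenerate circumcircle) at local index {idx}")
    n = n / nn[..., None]
    # circumcenter: C = N1 + x*ab + y*ac from the perpendicular-bisector system
    aa = np.einsum("...i,...i->...", ab, ab)
    cc = np.einsum("...i,...i->...", ac, ac)
    bc = np.einsum("...i,...i->...", ab, ac)
    det = aa * cc - bc * bc
    x = 0.5 * (aa * cc - cc * bc) / det
    y = 0.5 * (cc * aa - aa * bc) / det
    C = N1 + x[..., None] * ab + y[..., None] * ac
    r = np.linalg.norm(C - N1, axis=-1)
    return C, r, n, ab, ac


def simplex_height(r, d, phi):
    """Height ``L(r, d, phi)`` of a vertex above its neighbor plane.

    Evaluated in the sine/cosine form, which is finite at ``|phi| = pi/2``
    and needs no separate branch constant::

        A = r^2 cos^2(phi) + (r^2 - d^2) sin^2(phi)
        L = (r^2 - d^2) sin(phi) / (sqrt(A) + r cos(phi))      cos(phi) >= 0
        L = (sqrt(A) - r cos(phi)) / sin(phi)                  cos(phi) <  0

    The two branches are algebraically identical; the second avoids
    cancellation when ``cos(phi)`` is negative.  Returns ``nan`` where the
    parameterization is invalid (``d >= r``, a negative radicand, or
    ``phi = +-pi`` exactly).
    """
    r = np.asarray(r, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    s, c = np.sin(phi), np.cos(phi)
    r2d2 = r * r - d * d
    A = r * r * c * c + r2d2 * s * s
    invalid = (r2d2 <= 0) | (A < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sqrtA = np.sqrt(np.where(A < 0, np.nan, A))
        pos = r2d2 * s / (sqrtA + r * c)
        neg = (sqrtA - r * c) / s
    L = np.where(c >= 0, pos, neg)
    L = np.where(invalid | ~np.isfinite(L), np.nan, L)
    # phi == 0 must give exactly 0 even if d is at the validity edge
    L = np.where(s == 0, np.where(c > 0, 0.0, np.nan), L)
    if L.ndim == 0:
        return float(L)
    return L


def mesh_geometry(mesh: SimplexMesh) -> dict:
    """Vectorized local geometry for every vertex.

    Returns a dict of arrays keyed ``eps, F, n, C, r, O, R, d, phi, L, H``
    (first axis = vertex index).  The per-vertex wrapper
    :func:`vertex_geometry` and the greedy evolution both use this.
    """
    P = mesh.vertices
    N1 = P[mesh.neighbors[:, 0]]
    N2 = P[mesh.neighbors[:, 1]]
    N3 = P[mesh.neighbors[:, 2]]
    C, r, n, ab, ac = _triangle_frame(N1, N2, N3)

    L = np.einsum("ij,ij->i", P - N1, n)
    F = P - L[:, None] * n
    # barycentric coordinates of F in the neighbor triangle
    aa = np.einsum("ij,ij->i", ab, ab)
    cc = np.einsum("ij,ij->i", ac, ac)
    bc = np.einsum("ij,ij->i", ab, ac)
    det = aa * cc - bc * bc
    w = F - N1
    wa = np.einsum("ij,ij->i", w, ab)
    wc = np.einsum("ij,ij->i", w, ac)
    u = (cc * wa - bc * wc) / det
    v = (aa * wc - bc * wa) / det
    eps = np.stack([1.0 - u - v, u, v], axis=1)

    d = np.linalg.norm(F - C, axis=1)
    PC2 = np.einsum("ij,ij->i", P - C, P - C)
    phi = np.arctan2(2.0 * r * L, r * r - PC2)
    H = np.sin(phi) / r

    # circumsphere of the tetrahedron: center on the circumcircle axis
    flat = np.abs(L) < 1e-14 * np.maximum(r, 1.0)
    h = np.where(flat, 0.0, (PC2 - r * r) / np.where(L == 0, 1.0, 2.0 * L))
    O = C + h[:, None] * n
    R = np.sqrt(r * r + h * h)
    phi = np.where(flat, 0.0, phi)
    H = np.where(flat, 0.0, H)
    O[flat] = np.nan
    R = np.where(flat, np.inf, R)
    L = np.where(flat, 0.0, L)

    return {"eps": eps, "F": F, "n": n, "C": C, "r": r, "O": O, "R": R,
            "d": d, "phi": phi, "L": L, "H": H}


def vertex_geometry(mesh: SimplexMesh, i: int) -> VertexGeometry:
    """Local geometry of vertex ``i`` (see module docstring for conventions)."""
    P = mesh.vertices
    nb = mesh.neighbors[i]
    sub = SimplexMesh(
        np.vstack([P[i], P[nb[0]], P[nb[1]], P[nb[2]]]),
        np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 3]]),
    )
    g = mesh_geometry(sub)
    return VertexGeometry(
        eps=g["eps"][0], F=g["F"][0], n=g["n"][0], C=g["C"][0], r=float(g["r"][0]),
        O=g["O"][0], R=float(g["R"][0]), d=float(g["d"][0]), phi=float(g["phi"][0]),
        L=float(g["L"][0]), H=float(g["H"][0]),
    )


def reconstruct_position(geom: VertexGeometry, neighbors: np.ndarray) -> np.ndarray:
    """Rebuild a vertex from its metric parameters and simplex angle.

    ``P = eps1*N1 + eps2*N2 + eps3*N3 + L(r, d, phi) * n`` with the
    circumcircle quantities ``r, d`` and the normal ``n`` recomputed from the
    supplied neighbor triple (same ordering convention as
    :func:`vertex_geometry`).  Feeding a geometry back with its own neighbors
    reproduces the original position.
    """
    neighbors = np.asarray(neighbors, dtype=np.float64)
    N1, N2, N3 = neighbors
    C, r, n, _, _ = _triangle_frame(N1, N2, N3)
    F = geom.eps[0] * N1 + geom.eps[1] * N2 + geom.eps[2] * N3
    d = float(np.linalg.norm(F - C))
    L = simplex_height(float(r), d, geom.phi)
    if not np.isfinite(L):
        raise DegenerateGeometryError(
            f"height undefined for r={float(r):.6g}, d={d:.6g}, phi={geom.phi:.6g}")
    return F + L * n


def _check_closed_manifold(tri: trimesh.Trimesh) -> None:
    edges = np.sort(tri.edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    offending = uniq[counts != 2]
    if len(offending):
        e = offending[0]
        raise NonManifoldMeshError(
            f"mesh is not a closed 2-manifold: edge ({int(e[0])}, {int(e[1])}) "
            f"belongs to {int(counts[counts != 2][0])} faces (expected 2)")


def dual_simplex_from_triangles(tri: trimesh.Trimesh) -> SimplexMesh:
    """Dual 2-simplex mesh of a closed triangle mesh.

    One simplex vertex per triangle, placed at the triangle centroid (robust
    to obtuse triangles); two simplex vertices are neighbors iff their
    triangles share an edge.  Dual polygonal faces are the ordered triangle
    fans around each original vertex.  Neighbor order is chosen so the vertex
    normal points outward (same side as the triangle normal).
    """
    if not isinstance(tri, trimesh.Trimesh):
        tri = trimesh.Trimesh(vertices=np.asarray(tri.vertices),
                              faces=np.asarray(tri.faces), process=False)
    _check_closed_manifold(tri)
    areas = tri.area_faces
    if np.any(areas <= 0):
        raise NonManifoldMeshError(
            f"degenerate zero-area face at index {int(np.argmin(areas))}")
    if tri.volume < 0:
        tri = tri.copy()
        tri.invert()

    F = len(tri.faces)
    centroids = tri.triangles.mean(axis=1)

    # adjacency: faces sharing an edge
    adj = [[] for _ in range(F)]
    for (fa, fb) in tri.face_adjacency:
        adj[fa].append(int(fb))
        adj[fb].append(int(fa))
    neighbors = np.empty((F, 3), dtype=np.int64)
    for f in range(F):
        if len(adj[f]) != 3:
            raise NonManifoldMeshError(
                f"triangle {f} has {len(adj[f])} edge-adjacent triangles (expected 3)")
        neighbors[f] = adj[f]

    # orient neighbor order: normal from neighbor centroids must point the
    # same way as the triangle's own outward normal
    n1 = centroids[neighbors[:, 0]]
    n2 = centroids[neighbors[:, 1]]
    n3 = centroids[neighbors[:, 2]]
    dual_n = np.cross(n2 - n1, n3 - n1)
    flip = np.einsum("ij,ij->i", dual_n, tri.face_normals) < 0
    neighbors[flip] = neighbors[flip][:, [0, 2, 1]]

    faces = _dual_faces(tri)
    mesh = SimplexMesh(centroids, neighbors, faces)
    return mesh


def _dual_faces(tri: trimesh.Trimesh) -> list:
    """Ordered triangle fans around each vertex → dual polygon faces.

    A face with winding ``(v, p, q)`` owns the directed edges ``(v, p)``,
    ``(p, q)`` and ``(q, v)``; the fan around ``v`` is walked by stepping to
    the face that owns ``(v, q)`` (its neighbor across edge ``{v, q}``).
    """
    edge_face = {}
    for f, (a, b, c) in enumerate(tri.faces):
        edge_face[(int(a), int(b))] = f
        edge_face[(int(b), int(c))] = f
        edge_face[(int(c), int(a))] = f
    vertex_faces = [[] for _ in range(len(tri.vertices))]
    for f, fv in enumerate(tri.faces):
        for v in fv:
            vertex_faces[int(v)].append(f)
    faces = []
    for v, incident in enumerate(vertex_faces):
        if not incident:
            continue
        start = incident[0]
        cycle = []
        f = start
        while True:
            cycle.append(f)
            fv = [int(x) for x in tri.faces[f]]
            q = fv[(fv.index(v) + 2) % 3]  # vertex preceding v in winding
            f = edge_face.get((v, q))
            if f is None:
                raise NonManifoldMeshError(f"inconsistent winding around vertex {v}")
            if f == start:
                break
            if len(cycle) > len(incident):
                raise NonManifoldMeshError(f"vertex {v} has a non-disk face fan")
        if len(cycle) != len(incident):
            raise NonManifoldMeshError(f"vertex {v} has a non-disk face fan")
        faces.append(cycle)
    return faces


def save_simplex_mesh(mesh: SimplexMesh, path) -> None:
    """Write an ASCII PLY with polygonal faces plus a JSON neighbor sidecar.

    The sidecar (same stem, ``.json``) holds
    ``{"format": "simplexssm-neighbors", "neighbors": [[i1, i2, i3], ...]}``.
    """
    path = Path(path)
    V = mesh.n_vertices
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment 2-simplex mesh\n")
        fh.write(f"element vertex {V}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(str(len(f)) + " " + " ".join(str(int(i)) for i in f) + "\n")
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"format": "simplexssm-neighbors",
                   "neighbors": mesh.neighbors.tolist()}, fh)


def load_simplex_mesh(path) -> SimplexMesh:
    """Read a simplex mesh written by :func:`save_simplex_mesh`."""
    path = Path(path)
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unexpected end of PLY header")
            tok = line.split()
            if tok[:2] == ["element", "vertex"]:
                n_vert = int(tok[2])
            elif tok[:2] == ["element", "face"]:
                n_face = int(tok[2])
            elif tok[0] == "end_header":
                break
        vertices = np.array([[float(x) for x in fh.readline().split()]
                             for _ in range(n_vert)])
        faces = []
        for _ in range(n_face):
            tok = fh.readline().split()
            faces.append([int(x) for x in tok[1:1 + int(tok[0])]])
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    neighbors = np.asarray(meta["neighbors"], dtype=np.int64)
    return SimplexMesh(vertices, neighbors, faces)
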