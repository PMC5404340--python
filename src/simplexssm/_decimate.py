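"""Quadric-error edge-collapse mesh decimation.

Greedy Garland–Heckbert style simplification restricted to closed manifold
triangle meshes: repeatedly collapse the cheapest valid edge (link condition
enforced, degenerate faces skipped) until the face budget is met.  Each
interior-edge collapse on a closed mesh removes exactly two faces, so the
final face count lands exactly on the requested target (or one above it).
"""

from __future__ import annotations

import heapq

import numpy as np
import trimesh

__all__ = ["quadric_decimate"]


def _face_quadric(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm == 0:
        return np.zeros((4, 4))
    n = n / norm
    d = -np.dot(n, p0)
    plane = np.append(n, d)
    return np.outer(plane, plane) * norm  # area-weighted


def quadric_decimate(mesh: trimesh.Trimesh, target_faces: int) -> trimesh.Trimesh:
    if target_faces < 4:
        raise ValueError("a closed triangle mesh needs at least 4 faces")
    verts = [np.asarray(v, dtype=np.float64) for v in mesh.vertices]
    faces = {i: tuple(int(v) for v in f) for i, f in enumerate(mesh.faces)}
    vert_faces = {i: set() for i in range(len(verts))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)

    quadrics = [np.zeros((4, 4)) for _ in verts]
    for f in faces.values():
        K = _face_quadric(verts[f[0]], verts[f[1]], verts[f[2]])
        for v in f:
            quadrics[v] += K

    def neighbors(v):
        out = set()
        for fi in vert_faces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    def edge_cost(u, v):
        Q = quadrics[u] + quadrics[v]
        best = None
        for p in (verts[u], verts[v], 0.5 * (verts[u] + verts[v])):
            h = np.append(p, 1.0)
            c = float(h @ Q @ h)
            if best is None or c < best[0]:
                best = (c, p)
        return best

    heap = []
    version = {}

    def push_edge(u, v):
        a, b = (u, v) if u < v else (v, u)
        version[(a, b)] = version.get((a, b), 0) + 1
        cost, point = edge_cost(a, b)
        heapq.heappush(heap, (cost, version[(a, b)], a, b, point))

    seen = set()
    for f in faces.values():
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            a, b = (u, v) if u < v else (v, u)
            if (a, b) not in seen:
                seen.add((a, b))
                push_edge(a, b)

    alive = set(range(len(verts)))
    n_faces = len(faces)
    while n_faces > target_faces and heap:
        cost, ver, u, v, point = heapq.heappop(heap)
        if u not in alive or v not in alive:
            continue
        if version.get((u, v), -1) != ver:
            continue
        if v not in neighbors(u):
            continue
        # link condition: shared neighbors must be exactly the two opposite
        # vertices of the shared faces, otherwise the collapse pinches
        shared_faces = vert_faces[u] & vert_faces[v]
        if len(shared_faces) != 2:
            continue
        if len(neighbors(u) & neighbors(v)) != 2:
            continue
        if n_faces - 2 < target_faces:
            break
        # collapse v into u, move u to the optimal point
        verts[u] = np.asarray(point, dtype=np.float64)
        quadrics[u] = quadrics[u] + quadrics[v]
        for fi in shared_faces:
            for w in faces[fi]:
                if w not in (u, v):
                    vert_faces[w].discard(fi)
            del faces[fi]
        vert_faces[u] -= shared_faces
        vert_faces[v] -= shared_faces
        for fi in list(vert_faces[v]):
            f = faces[fi]
            faces[fi] = tuple(u if w == v else w for w in f)
            vert_faces[u].add(fi)
        vert_faces[v] = set()
        alive.discard(v)
        n_faces -= 2
        for w in neighbors(u):
            push_edge(u, w)

    remap = {old: new for new, old in enumerate(sorted(alive))}
    new_verts = np.array([verts[old] for old in sorted(alive)])
    new_faces = np.array([[remap[w] for w in f] for f in faces.values()])
    out = trimesh.Trimesh(vertices=new_verts, faces=new_faces, process=False)
    return out
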