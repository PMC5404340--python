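"""Greedy evolution of a deformable 2-simplex mesh.

Per iteration, every vertex exhaustively scores candidate positions — the
``w^3`` voxel centers of a cubic window around the voxel containing the
vertex, plus the current (continuous) position so "no move" is always
available.  The score combines

* internal energy: tangential term (distance of the tangent-plane projection
  from the neighbor centroid — drives uniform vertex spacing) plus normal
  term (squared height mismatch against the reference simplex angle, the
  mean of the three neighbors' angles — a C2 smoothness prior),
* external energy: the sampled VFC magnitude itself — the field vectors
  cancel on the boundary (force equilibrium), so edge voxels are already
  energy minima,

each min-max normalized over the window (a constant set normalizes to
zeros, making the weights ``alpha``/``beta`` scale-free), summed as
``alpha * E_int + beta * E_ext``.  The winning candidate ``Q`` moves the
vertex only along its normal: ``P <- P + ((Q - P) . n) n``.  All updates in
one iteration are computed from the pre-step mesh (synchronous), so the
result is independent of vertex order.

Ties in the argmin are broken by smallest distance to the current position
(hence the no-move candidate wins an all-equal window), then by candidate
index in window order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EvolutionDivergedError
from .mesh import SimplexMesh, mesh_geometry, simplex_height
from .vfc import VFCEnergyVolume, sample_energy

__all__ = [
    "EvolutionParams", "EvolutionReport", "window_candidates",
    "internal_energy", "candidate_energy", "greedy_step", "evolve",
]

_INF = np.inf


@dataclass
class EvolutionParams:
    """Tunables of the greedy evolution.

    ``alpha``/``beta`` weight internal vs external energy; ``w`` is the odd
    cubic window width in voxels; ``move_tol`` (mm) is the convergence
    threshold on the largest per-iteration vertex displacement.
    """

    alpha: float = 0.4
    beta: float = 1.0
    w: int = 11
    max_iters: int = 200
    move_tol: float = 0.1
    log_every: int = 10

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError("window width w must be odd and >= 3")


@dataclass
class EvolutionReport:
    """Per-iteration record of an evolution run."""

    iterations: int = 0
    max_displacements: list = field(default_factory=list)  # mm, one per iter
    converged: bool = False


def window_candidates(ev: VFCEnergyVolume, p: np.ndarray, w: int) -> np.ndarray:
    """The ``w^3`` voxel centers around the voxel containing ``p``, plus
    ``p`` itself as the last candidate (window order = nested x, y, z)."""
    spacing = np.asarray(ev.spacing)
    origin = np.asarray(ev.origin)
    vi = np.round((np.asarray(p, dtype=np.float64) - origin) / spacing)
    half = (w - 1) // 2
    off = np.arange(-half, half + 1, dtype=np.float64)
    OX, OY, OZ = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([OX, OY, OZ], axis=-1).reshape(-1, 3)
    cands = origin + (vi + offsets) * spacing
    return np.vstack([cands, np.asarray(p, dtype=np.float64)])


def _internal_energy_batch(cand, N1, N2, N3, C, r, n, phi_ref):
    """Internal energy for candidates ``cand`` (..., K, 3) with the neighbor
    frame held fixed; degenerate configurations get an inf sentinel."""
    L = np.einsum("...ki,...i->...k", cand - N1[..., None, :], n)
    F = cand - L[..., None] * n[..., None, :]
    G = (N1 + N2 + N3) / 3.0
    e_tan = np.einsum("...ki,...ki->...k", F - G[..., None, :], F - G[..., None, :])
    d = np.linalg.norm(F - C[..., None, :], axis=-1)
    with np.errstate(invalid="ignore"):
        L_target = simplex_height(r[..., None], d, phi_ref[..., None])
    e_norm = (np.asarray(L_target) - L) ** 2
    e = e_tan + e_norm
    return np.where(np.isfinite(e), e, _INF)


def _minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Min-max normalize along the last axis, ignoring inf sentinels.

    Constant (or all-inf) windows normalize to zeros; inf stays inf.
    """
    finite = np.isfinite(x)
    big = np.where(finite, x, np.nan)
    with np.errstate(all="ignore"):
        lo = np.nanmin(big, axis=-1, keepdims=True)
        hi = np.nanmax(big, axis=-1, keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    out = np.where(finite, out, _INF)
    out = np.where(np.isnan(out), _INF, out)
    return out


def _mesh_frames(mesh: SimplexMesh):
    geo = mesh_geometry(mesh)
    P = mesh.vertices
    nb = mesh.neighbors
    phi_ref = geo["phi"][nb].mean(axis=1)
    return (P, P[nb[:, 0]], P[nb[:, 1]], P[nb[:, 2]],
            geo["C"], geo["r"], geo["n"], phi_ref)


def internal_energy(mesh: SimplexMesh, i: int, candidate: np.ndarray) -> float:
    """Internal energy of moving vertex ``i`` to ``candidate`` with its
    neighbors frozen at their current positions (mm^2)."""
    P, N1, N2, N3, C, r, n, phi_ref = _mesh_frames(mesh)
    cand = np.asarray(candidate, dtype=np.float64)[None, :]
    e = _internal_energy_batch(cand, N1[i], N2[i], N3[i], C[i], r[i], n[i],
                               phi_ref[i])
    return float(e[0])


def candidate_energy(mesh: SimplexMesh, i: int, window_cands: np.ndarray,
                     ev: VFCEnergyVolume, params: EvolutionParams) -> dict:
    """Scores of all window candidates for vertex ``i``.

    Returns ``{"internal_raw", "external_raw", "internal", "external",
    "score"}`` arrays (window order; the raw external energy is the sampled
    VFC magnitude)."""
    P, N1, N2, N3, C, r, n, phi_ref = _mesh_frames(mesh)
    cand = np.asarray(window_cands, dtype=np.float64)
    e_int = _internal_energy_batch(cand, N1[i], N2[i], N3[i], C[i], r[i], n[i],
                                   phi_ref[i])
    e_ext = np.asarray(sample_energy(ev, cand))
    n_int = _minmax_normalize(e_int)
    n_ext = _minmax_normalize(e_ext)
    score = params.alpha * n_int + params.beta * n_ext
    return {"internal_raw": e_int, "external_raw": e_ext,
            "internal": n_int, "external": n_ext, "score": score}


def _select(cand, score, P):
    """Argmin with tie-break: score, then distance to ``P``, then index."""
    dist = np.linalg.norm(cand - P[..., None, :], axis=-1)
    K = score.shape[-1]
    idx = np.broadcast_to(np.arange(K, dtype=np.float64), score.shape)
    order = np.lexsort(np.stack([idx, dist, score]), axis=-1)
    return order[..., 0]


def greedy_step(mesh: SimplexMesh, ev: VFCEnergyVolume,
                params: EvolutionParams, chunk_size: int = 512):
    """One synchronous greedy iteration.  Returns ``(new_mesh, max_disp)``."""
    P, N1, N2, N3, C, r, n, phi_ref = _mesh_frames(mesh)
    V = mesh.n_vertices
    spacing = np.asarray(ev.spacing)
    origin = np.asarray(ev.origin)
    half = (params.w - 1) // 2
    off = np.arange(-half, half + 1, dtype=np.float64)
    OX, OY, OZ = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.stack([OX, OY, OZ], axis=-1).reshape(-1, 3)

    new_P = np.empty_like(P)
    max_disp = 0.0
    for s in range(0, V, chunk_size):
        sl = slice(s, min(s + chunk_size, V))
        Pc = P[sl]
        vi = np.round((Pc - origin) / spacing)
        cand = origin + (vi[:, None, :] + offsets[None, :, :]) * spacing
        cand = np.concatenate([cand, Pc[:, None, :]], axis=1)
        e_int = _internal_energy_batch(cand, N1[sl], N2[sl], N3[sl],
                                       C[sl], r[sl], n[sl], phi_ref[sl])
        e_ext = sample_energy(ev, cand.reshape(-1, 3)).reshape(cand.shape[:2])
        score = (params.alpha * _minmax_normalize(e_int)
                 + params.beta * _minmax_normalize(e_ext))
        pick = _select(cand, score, Pc)
        Q = cand[np.arange(len(Pc)), pick]
        along = np.einsum("ij,ij->i", Q - Pc, n[sl])
        new_P[sl] = Pc + along[:, None] * n[sl]
        if len(along):
            max_disp = max(max_disp, float(np.abs(along).max()))

    out = SimplexMesh(new_P, mesh.neighbors.copy(), [list(f) for f in mesh.faces])
    return out, max_disp


def evolve(mesh: SimplexMesh, ev: VFCEnergyVolume, params: EvolutionParams,
           log=None):
    """Iterate :func:`greedy_step` to convergence.

    Stops when the largest displacement falls below ``params.move_tol`` or
    after ``params.max_iters`` iterations.  Raises
    :class:`EvolutionDivergedError` if the displacement grows for 10
    consecutive iterations.
    """
    report = EvolutionReport()
    current = mesh
    growing = 0
    for it in range(params.max_iters):
        current, disp = greedy_step(current, ev, params)
        report.iterations = it + 1
        report.max_displacements.append(disp)
        if log is not None and params.log_every and (it % params.log_every == 0):
            log(f"iteration {it}: max displacement {disp:.4f} mm")
        if disp < params.move_tol:
            report.converged = True
            break
        if len(report.max_displacements) >= 2 and \
                disp > report.max_displacements[-2]:
            growing += 1
            if growing >= 10:
                raise EvolutionDivergedError(
                    f"displacement grew for {growing} consecutive iterations "
                    f"(last {disp:.4f} mm at iteration {it})")
        else:
            growing = 0
    return current, report
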