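"""Affine initialization by Gaussian-mixture L2 registration.

Template and target point sets (mesh vertices) are represented as isotropic
Gaussian mixtures; the affine map ``x -> A x + t`` with ``A = Q S`` (``Q``
orthogonal, ``S`` symmetric positive definite) is found by minimizing the L2
distance between the transformed template mixture and the target mixture.
Both remaining integrals (the target self-term is transformation independent
and dropped) have closed forms built from the Gaussian product integral

    int phi(x | m1, s1^2 I) phi(x | m2, s2^2 I) dx
        = phi(0 | m1 - m2, (s1^2 + s2^2) I),

which for isotropic components is exact under the affine map because the
transformed covariance ``Q (s^2 I) Q^T = s^2 I``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .mesh import SimplexMesh

__all__ = [
    "GaussianMixtureShape", "AffineTransform", "mesh_to_gmm", "l2_objective",
    "register_affine", "select_template", "apply_affine",
]


@dataclass
class GaussianMixtureShape:
    """Isotropic, equal-covariance Gaussian mixture over a point set.

    One component per point; ``scale`` is the shared standard deviation (mm).
    """

    means: np.ndarray      # (m, 3) component means, mm
    weights: np.ndarray    # (m,) nonnegative, sum to 1
    scale: float           # isotropic std dev, mm

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {s}")


@dataclass
class AffineTransform:
    """Affine map ``x -> A x + t`` with the polar factorization ``A = Q S``."""

    Q: np.ndarray   # 3x3 orthogonal
    S: np.ndarray   # 3x3 symmetric positive definite
    t: np.ndarray   # translation, mm

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        self.t = np.asarray(self.t, dtype=np.float64)
        if np.max(np.abs(self.Q.T @ self.Q - np.eye(3))) > 1e-9:
            raise ValueError("Q is not orthogonal")
        if np.max(np.abs(self.S - self.S.T)) > 1e-9:
            raise ValueError("S is not symmetric")
        if np.min(np.linalg.eigvalsh(self.S)) <= 0:
            raise ValueError("S is not positive definite")

    @property
    def A(self) -> np.ndarray:
        return self.Q @ self.S

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.eye(3), np.zeros(3))

    @classmethod
    def from_A(cls, A: np.ndarray, t: np.ndarray) -> "AffineTransform":
        """Polar-decompose a general (invertible, det>0) matrix into Q S."""
        A = np.asarray(A, dtype=np.float64)
        U, sv, Vt = np.linalg.svd(A)
        Q = U @ Vt
        S = Vt.T @ np.diag(sv) @ Vt
        return cls(Q, S, np.asarray(t, dtype=np.float64))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.A.T + self.t

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Map equal to applying ``other`` first, then ``self``."""
        return AffineTransform.from_A(self.A @ other.A, self.A @ other.t + self.t)


def mesh_to_gmm(mesh: SimplexMesh, scale: float,
                max_components: int | None = None) -> GaussianMixtureShape:
    """Uniform-weight mixture with one component per mesh vertex.

    ``max_components`` caps the mixture size by deterministic uniform-stride
    subsampling (cost of the cross term is O(m n)).
    """
    pts = mesh.vertices if isinstance(mesh, SimplexMesh) else np.asarray(mesh)
    if len(pts) == 0:
        raise ValueError("mesh has no vertices")
    if max_components is not None and len(pts) > max_components:
        stride = int(np.ceil(len(pts) / max_components))
        pts = pts[::stride]
    m = len(pts)
    return GaussianMixtureShape(pts.copy(), np.full(m, 1.0 / m), float(scale))


def _gauss0(diff: np.ndarray, var: float) -> np.ndarray:
    """phi(0 | diff, var * I) for rows of ``diff`` (3-D isotropic)."""
    sq = np.einsum("...i,...i->...", diff, diff)
    return (2.0 * np.pi * var) ** -1.5 * np.exp(-0.5 * sq / var)


def l2_objective(f: GaussianMixtureShape, g: GaussianMixtureShape,
                 T: AffineTransform) -> float:
    """Transformation-dependent part of the L2 distance between mixtures.

    Returns ``int f_{A,t}^2 - 2 int f_{A,t} g``; the ``int g^2`` term is
    constant in ``(A, t)`` and omitted.  Add it back (via ``l2_objective(g,
    g, identity)``-style self-terms) to obtain the full nonnegative distance.
    """
    mu = T.apply(f.means)
    # self term: pairwise over transformed template components
    diff_ff = mu[:, None, :] - mu[None, :, :]
    wf = f.weights
    term_ff = float(wf @ _gauss0(diff_ff, 2.0 * f.scale ** 2) @ wf)
    # cross term against the (untransformed) target mixture
    diff_fg = mu[:, None, :] - g.means[None, :, :]
    term_fg = float(wf @ _gauss0(diff_fg, f.scale ** 2 + g.scale ** 2) @ g.weights)
    return term_ff - 2.0 * term_fg


def gmm_self_term(g: GaussianMixtureShape) -> float:
    """``int g^2`` — the constant completing :func:`l2_objective` to d_L2."""
    diff = g.means[:, None, :] - g.means[None, :, :]
    return float(g.weights @ _gauss0(diff, 2.0 * g.scale ** 2) @ g.weights)


def _objective_and_grad(x: np.ndarray, f: GaussianMixtureShape,
                        g: GaussianMixtureShape):
    """Closed-form objective and its analytic gradient in the unconstrained
    parameterization ``x = [vec(A), t]`` (isotropic covariances make the
    objective a function of ``A`` only, so no SPD constraint is needed
    during optimization)."""
    A = x[:9].reshape(3, 3)
    t = x[9:12]
    wf, wg = f.weights, g.weights
    v_ff = 2.0 * f.scale ** 2
    v_fg = f.scale ** 2 + g.scale ** 2

    D = f.means[:, None, :] - f.means[None, :, :]       # (m, m, 3)
    M_ff = D @ A.T
    G_ff = _gauss0(M_ff, v_ff)
    W_ff = wf[:, None] * wf[None, :] * G_ff
    term_ff = float(W_ff.sum())
    gA_ff = -np.einsum("pq,pqi,pqj->ij", W_ff, M_ff, D) / v_ff

    mu = f.means @ A.T + t
    M_fg = mu[:, None, :] - g.means[None, :, :]         # (m, n, 3)
    G_fg = _gauss0(M_fg, v_fg)
    W_fg = wf[:, None] * wg[None, :] * G_fg
    term_fg = float(W_fg.sum())
    gA_fg = -np.einsum("pq,pqi,pj->ij", W_fg, M_fg, f.means) / v_fg
    gt_fg = -np.einsum("pq,pqi->i", W_fg, M_fg) / v_fg

    obj = term_ff - 2.0 * term_fg
    grad = np.concatenate([(gA_ff - 2.0 * gA_fg).ravel(), -2.0 * gt_fg])
    return obj, grad


def register_affine(template: GaussianMixtureShape, target: GaussianMixtureShape,
                    init: AffineTransform | None = None,
                    scale_schedule: tuple = (4.0, 1.0),
                    tol: float = 1e-12, max_iter: int = 200) -> AffineTransform:
    """Quasi-Newton (L-BFGS) minimization of the L2 objective.

    The 12 parameters are the raw affine entries plus the translation, with
    analytic gradients; the result is polar-factorized into ``Q S`` at the
    end.  A coarse-to-fine schedule multiplies both mixture scales before a
    final pass at the nominal scales, which widens the basin of attraction
    from an identity start.
    """
    if init is None:
        init = AffineTransform.identity()
    x0 = np.concatenate([init.A.ravel(), init.t])
    for factor in scale_schedule:
        f = GaussianMixtureShape(template.means, template.weights,
                                 template.scale * factor)
        g = GaussianMixtureShape(target.means, target.weights,
                                 target.scale * factor)
        result = minimize(_objective_and_grad, x0, args=(f, g), jac=True,
                          method="L-BFGS-B", tol=tol,
                          options={"maxiter": max_iter})
        x0 = result.x
    T = AffineTransform.from_A(x0[:9].reshape(3, 3), x0[9:12])
    # never accept an uphill final state
    if l2_objective(template, target, T) > l2_objective(template, target, init) + 1e-15:
        return init
    return T


def apply_affine(mesh: SimplexMesh, T: AffineTransform) -> SimplexMesh:
    """Map every vertex through ``x -> A x + t``; connectivity unchanged."""
    out = mesh.copy()
    out.vertices = T.apply(mesh.vertices)
    return out


def select_template(meshes: list, scale: float | None = None,
                    max_components: int = 250, max_iter: int = 60) -> int:
    """Index of the most average sample.

    Registers every sample to every other (K(K-1) pairwise registrations)
    and returns the index minimizing the sum of post-registration L2
    objectives (first index wins ties).  Only the *ranking* matters here, so
    the mixtures are subsampled harder and the optimizer budget is smaller
    than for the final per-target initializations.
    """
    if len(meshes) < 2:
        raise ValueError("template selection needs at least 2 meshes")
    gmms = []
    for m in meshes:
        s = scale if scale is not None else _mean_edge_length(m)
        gmms.append(mesh_to_gmm(m, s, max_components=max_components))
    totals = []
    for i, f in enumerate(gmms):
        total = 0.0
        for j, g in enumerate(gmms):
            if i == j:
                continue
            T = register_affine(f, g, max_iter=max_iter, tol=1e-9)
            total += l2_objective(f, g, T) + gmm_self_term(g)
        totals.append(total)
    return int(np.argmin(totals))


def _mean_edge_length(mesh: SimplexMesh) -> float:
    e = mesh.edges()
    d = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return float(d.mean())
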