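"""Generalized Procrustes alignment and the PCA statistical shape model.

Corresponded shapes are 3N-dimensional landmark vectors (landmark ``k`` at
components ``3k..3k+2``, mm).  GPA aligns them into a common frame
(translation + rotation; scaling off by default so the model stays in mm).
The model is the eigen-decomposition of the sample covariance
``S = 1/(K-1) * sum (x_i - mean)(x_i - mean)^T``, computed through the K x K
Gram (dual) eigenproblem when ``3N > K``; the retained mode count ``c`` is
the smallest t with cumulative/total variance ratio strictly above 0.98.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import orthogonal_procrustes

logger = logging.getLogger(__name__)

__all__ = ["ShapeModel", "gpa_align", "build_model", "synthesize", "project",
           "save_model", "load_model"]

VARIANCE_THRESHOLD = 0.98


def _as_matrix(shapes) -> np.ndarray:
    X = np.asarray(shapes, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("shapes must be a (K, 3N) array or list of vectors")
    if X.shape[1] % 3:
        raise ValueError("shape vector length must be divisible by 3")
    return X


def _align_one(x: np.ndarray, ref: np.ndarray, with_scaling: bool) -> np.ndarray:
    """Procrustes-align landmark vector ``x`` to ``ref`` (both centered)."""
    Xp = x.reshape(-1, 3)
    Rp = ref.reshape(-1, 3)
    R, s = orthogonal_procrustes(Xp, Rp)
    out = Xp @ R
    if with_scaling:
        denom = (Xp * Xp).sum()
        out = out * (s / denom if denom > 0 else 1.0)
    return out.ravel()


def gpa_align(shapes, with_scaling: bool = False, tol: float = 1e-8,
              max_iter: int = 100) -> np.ndarray:
    """Generalized Procrustes analysis.

    Centroids are translated to the origin, then each shape is iteratively
    rotated (and optionally scaled) onto the running mean until the mean
    stops changing.  Returns the aligned ``(K, 3N)`` array.
    """
    X = _as_matrix(shapes).copy()
    if len(X) < 2:
        raise ValueError("GPA needs at least 2 shapes")
    K, D = X.shape
    # center
    pts = X.reshape(K, -1, 3)
    pts = pts - pts.mean(axis=1, keepdims=True)
    X = pts.reshape(K, D)
    mean = X[0].copy()
    for _ in range(max_iter):
        X = np.stack([_align_one(x, mean, with_scaling) for x in X])
        new_mean = X.mean(axis=0)
        if with_scaling:
            nrm = np.linalg.norm(new_mean)
            if nrm > 0:
                new_mean = new_mean / nrm * np.linalg.norm(mean)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    return X


@dataclass
class ShapeModel:
    """Mean shape + PCA modes of variation.

    ``modes`` columns are orthonormal; ``eigenvalues`` (mm^2) descending;
    ``c`` is the 98%-variance retained-mode count; ``K`` training shapes of
    ``N`` landmarks each.
    """

    mean: np.ndarray         # (3N,)
    modes: np.ndarray        # (3N, n_modes)
    eigenvalues: np.ndarray  # (n_modes,)
    c: int
    K: int
    N: int

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def build_model(aligned, method: str = "auto") -> ShapeModel:
    """PCA shape model from aligned shape vectors.

    ``method``: ``'dual'`` solves the K x K Gram eigenproblem (used
    automatically when ``3N > K``), ``'direct'`` the full 3N x 3N covariance;
    both give identical nonzero eigenpairs.  Eigenvector signs are fixed by
    making the largest-magnitude component positive.
    """
    X = _as_matrix(aligned)
    K, D = X.shape
    if K < 2:
        raise ValueError("model building needs at least 2 shapes")
    mean = X.mean(axis=0)
    Xc = X - mean
    if method == "auto":
        method = "dual" if D > K else "direct"
    if method == "dual":
        G = Xc @ Xc.T / (K - 1)
        lam, U = np.linalg.eigh(G)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        U = U[:, order]
        modes = Xc.T @ U  # (D, K)
        norms = np.linalg.norm(modes, axis=0)
        keep = norms > 1e-12 * max(norms.max(), 1.0)
        modes = modes[:, keep] / norms[keep]
        lam = np.clip(lam[keep], 0.0, None)
        n_keep = min(K - 1, modes.shape[1])
        modes, lam = modes[:, :n_keep], lam[:n_keep]
    elif method == "direct":
        S = Xc.T @ Xc / (K - 1)
        lam, modes = np.linalg.eigh(S)
        order = np.argsort(lam)[::-1][:max(K - 1, 1)]
        lam = np.clip(lam[order], 0.0, None)
        modes = modes[:, order]
        nz = lam > 1e-12 * max(lam.max(), 1.0) if lam.size else np.zeros(0, bool)
        modes, lam = modes[:, nz], lam[nz]
    else:
        raise ValueError(f"unknown method {method!r}")

    # reproducible eigenvector signs
    for m in range(modes.shape[1]):
        j = int(np.argmax(np.abs(modes[:, m])))
        if modes[j, m] < 0:
            modes[:, m] = -modes[:, m]

    total = lam.sum()
    if total <= 0:
        c = 0
    else:
        ratio = np.cumsum(lam) / total
        above = np.nonzero(ratio > VARIANCE_THRESHOLD)[0]
        c = int(above[0]) + 1 if len(above) else len(lam)
    return ShapeModel(mean=mean, modes=modes, eigenvalues=lam, c=c, K=K,
                      N=D // 3)


def synthesize(model: ShapeModel, b) -> np.ndarray:
    """``mean + sum b_m * mode_m`` with each coefficient clamped to
    ``[-3 sqrt(lambda_m), +3 sqrt(lambda_m)]`` (clamping is logged)."""
    b = np.atleast_1d(np.asarray(b, dtype=np.float64))
    if len(b) > model.n_modes:
        raise ValueError(f"{len(b)} coefficients but only {model.n_modes} modes")
    bound = 3.0 * np.sqrt(model.eigenvalues[:len(b)])
    clamped = np.clip(b, -bound, bound)
    if np.any(clamped != b):
        logger.info("synthesize: %d coefficient(s) clamped to +-3 sqrt(lambda)",
                    int(np.sum(clamped != b)))
    return model.mean + model.modes[:, :len(b)] @ clamped


def project(model: ShapeModel, x: np.ndarray, M: int | None = None) -> np.ndarray:
    """Least-squares mode coefficients ``b_m = mode_m . (x - mean)`` for the
    first ``M`` modes (all modes when ``M`` is None)."""
    if M is None:
        M = model.n_modes
    if M > model.n_modes:
        raise ValueError(f"M={M} exceeds available modes ({model.n_modes})")
    return model.modes[:, :M].T @ (np.asarray(x, dtype=np.float64) - model.mean)


def save_model(model: ShapeModel, path) -> None:
    """Single-file ``.npz`` with mean, modes, eigenvalues, c, K, N."""
    np.savez(Path(path), mean=model.mean, modes=model.modes,
             eigenvalues=model.eigenvalues,
             meta=np.array([model.c, model.K, model.N], dtype=np.int64))


def load_model(path) -> ShapeModel:
    z = np.load(Path(path))
    c, K, N = (int(v) for v in z["meta"])
    return ShapeModel(mean=z["mean"], modes=z["modes"],
                      eigenvalues=z["eigenvalues"], c=c, K=K, N=N)
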