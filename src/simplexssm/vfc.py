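"""Vector field convolution (VFC) external energy.

The external energy that drives the deformable mesh is the magnitude of the
VFC field: the edge map (gradient magnitude of the Gaussian-blurred volume,
min-max normalized to [0, 1]) convolved with a vector kernel whose vectors
point toward the kernel origin with a distance-decaying magnitude.  The kernel
vectors cancel where edge contributions surround a point symmetrically, so
the magnitude has a sharp minimum on the object boundary (the force
equilibrium of the underlying field) — which is exactly what the greedy
evolution minimizes.  Large kernel radii relative to the object wash this
minimum out (the far side of a closed boundary dominates); radii of about
half the object diameter or less keep it crisp.

Energy volumes carry the saturation value ``max_energy``: sampling outside
the grid returns it, which keeps the mesh from drifting out of the volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .volume import LabelVolume

__all__ = [
    "EdgeMap", "VFCKernel", "VFCEnergyVolume",
    "compute_edge_map", "build_kernel", "compute_vfc_field",
    "energy_from_field", "sample_energy",
]


@dataclass
class EdgeMap:
    """Scalar boundary-likelihood grid in [0, 1] with volume metadata."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)


@dataclass
class VFCKernel:
    """Discrete vector field kernel on a (2R+1)^3 grid (voxel units).

    ``grid[x, y, z]`` is ``m(x, y, z) * n(x, y, z)`` with ``n`` the unit
    vector pointing from ``(x, y, z)`` toward the origin, ``n(0) = 0``.
    Magnitudes: ``m1 = (r + eps_div)^-gamma`` (default, heavy-tailed) or
    ``m2 = exp(-r^2 / zeta^2)`` (Gaussian).
    """

    radius: int
    magnitude_kind: str = "m1"
    gamma: float = 1.7
    zeta: float = 1.0
    eps_div: float = 1e-8
    grid: np.ndarray = None  # (2R+1, 2R+1, 2R+1, 3)


def compute_edge_map(vol: LabelVolume, sigma: float = 1.0) -> EdgeMap:
    """``|grad(G_sigma * I)|`` normalized to [0, 1].

    ``sigma`` is in voxels; gradients are spacing-aware (per-mm), so
    anisotropic voxels weight the axes correctly.  An identically-zero map is
    returned as all zeros.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    data = np.asarray(vol.data, dtype=np.float64)
    blurred = ndimage.gaussian_filter(data, sigma) if sigma > 0 else data
    grads = np.gradient(blurred, *vol.spacing)
    mag = np.sqrt(sum(g * g for g in grads))
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return EdgeMap(mag, vol.spacing, vol.origin, sigma)


def build_kernel(R: int, magnitude_kind: str = "m1", gamma: float = 1.7,
                 zeta: float = 1.0, eps_div: float = 1e-8) -> VFCKernel:
    """Discrete VFC kernel of radius ``R`` voxels."""
    if R < 1:
        raise ValueError("kernel radius must be >= 1")
    if magnitude_kind not in ("m1", "m2"):
        raise ValueError(f"unknown magnitude kind {magnitude_kind!r}")
    if magnitude_kind == "m1" and gamma <= 0:
        raise ValueError("gamma must be positive for m1")
    if magnitude_kind == "m2" and zeta <= 0:
        raise ValueError("zeta must be positive for m2")
    ax = np.arange(-R, R + 1, dtype=np.float64)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X * X + Y * Y + Z * Z)
    if magnitude_kind == "m1":
        m = (r + eps_div) ** -gamma
    else:
        m = np.exp(-(r * r) / (zeta * zeta))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(r > 0, 1.0 / r, 0.0)
    grid = np.stack([-X * inv_r, -Y * inv_r, -Z * inv_r], axis=-1)
    grid *= m[..., None]
    grid[R, R, R] = 0.0
    return VFCKernel(R, magnitude_kind, gamma, zeta, eps_div, grid)


def compute_vfc_field(edge: EdgeMap, kernel: VFCKernel,
                      method: str = "fft") -> np.ndarray:
    """Zero-padded linear convolution of the edge map with each kernel
    component, cropped to the edge-map grid.  Returns ``(nx, ny, nz, 3)``.

    ``method='direct'`` uses the spatial-domain convolution (slow; used as an
    independent cross-check on small grids).
    """
    data = edge.data
    k = kernel.grid
    if any(ks > 2 * ds for ks, ds in zip(k.shape[:3], data.shape)):
        crop = min((2 * min(data.shape) - 1 - 1) // 2, kernel.radius)
        crop = max(crop, 1)
        warnings.warn(
            f"VFC kernel radius {kernel.radius} exceeds twice the volume "
            f"extent {data.shape}; cropping kernel to radius {crop}")
        R = kernel.radius
        sl = slice(R - crop, R + crop + 1)
        k = k[sl, sl, sl]
    mode = "same"
    field = np.empty(data.shape + (3,))
    for c in range(3):
        if method == "fft":
            field[..., c] = fftconvolve(data, k[..., c], mode=mode)
        elif method == "direct":
            field[..., c] = ndimage.convolve(
                data, k[..., c], mode="constant", cval=0.0)
        else:
            raise ValueError(f"unknown method {method!r}")
    return field


@dataclass
class VFCEnergyVolume:
    """Precomputed scalar external-energy grid (VFC field magnitude)."""

    energy: np.ndarray
    max_energy: float
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def to_volume(self) -> LabelVolume:
        """Wrap as a (non-binary) volume for NIfTI/MetaImage persistence."""
        return LabelVolume(self.energy, self.spacing, self.origin)


def energy_from_field(field: np.ndarray, spacing=(1.0, 1.0, 1.0),
                      origin=(0.0, 0.0, 0.0)) -> VFCEnergyVolume:
    """Voxelwise Euclidean magnitude of the VFC field."""
    energy = np.linalg.norm(np.asarray(field), axis=-1)
    return VFCEnergyVolume(energy, float(energy.max()) if energy.size else 0.0,
                           spacing, origin)


def sample_energy(ev: VFCEnergyVolume, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the energy at world points (mm).

    Points outside the grid return ``max_energy`` — the worst possible
    score, which pushes the mesh back inside the volume.
    """
    pts = np.asarray(pts, dtype=np.float64)
    single = pts.ndim == 1
    pts2 = np.atleast_2d(pts)
    idx = (pts2 - np.asarray(ev.origin)) / np.asarray(ev.spacing)
    shape = np.asarray(ev.energy.shape)
    outside = np.any((idx < 0) | (idx > shape - 1), axis=-1)
    coords = np.clip(idx, 0, shape - 1).T
    vals = ndimage.map_coordinates(ev.energy, coords, order=1, mode="nearest")
    vals[outside] = ev.max_energy
    return float(vals[0]) if single else vals
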