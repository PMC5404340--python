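"""Deterministic synthetic shapes: the package's training-data generators.

Every test surface is generated programmatically: digitized ellipsoids, a
parametric shape family with known linear deformation modes (ground-truth
surfaces and correspondences included), and toy edge maps.  The family
stands in for a set of segmented anatomical scans: the base shape is an
ellipsoid and each mode is a smooth radial displacement field driven by a
low-order spherical-harmonic-like pattern, so the digitized surfaces stay
genus-0 and marching cubes stays clean.

A surface point in direction ``u`` (unit vector) is
``v(u) = (1 + sum_k b_k psi_k(u)) * (a ⊙ u)`` with semi-axes ``a`` and
coefficients ``b_k ~ N(0, lambda_k)``; a voxel center ``p`` is inside iff
``||p ⊘ a|| <= 1 + sum_k b_k psi_k(unit(p ⊘ a))``.  The same modes evaluated
on a fixed icosphere give ground-truth landmark meshes in exact
correspondence, so model-recovery tests have closed-form expectations.

All generators are pure functions of their spec + seed (bitwise
reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .vfc import EdgeMap
from .volume import LabelVolume

logger = logging.getLogger(__name__)

__all__ = ["ShapeFamilySpec", "make_ellipsoid_volume", "make_shape_family",
           "make_point_source_edge_map", "family_surface_distance",
           "MODE_PATTERNS"]


def _y20(u):
    return 0.5 * (3.0 * u[..., 2] ** 2 - 1.0)


def _y22(u):
    return np.sqrt(3.0) * u[..., 0] * u[..., 1]


def _y21(u):
    return np.sqrt(3.0) * u[..., 0] * u[..., 2]


def _bulge_x(u):
    # one-sided smooth bump on the +x pole
    return np.clip(u[..., 0], 0.0, None) ** 2


MODE_PATTERNS = {"y20": _y20, "y21": _y21, "y22": _y22, "bulge_x": _bulge_x}


@dataclass
class ShapeFamilySpec:
    """Specification of a synthetic shape family.

    ``modes`` maps pattern names (keys of ``MODE_PATTERNS``) to standard
    deviations ``sqrt(lambda*)`` of the radial-scale coefficients
    (dimensionless, i.e. relative radius change).  ``noise_sigma`` adds
    seeded landmark jitter (mm) to the ground-truth meshes only.
    """

    semi_axes: tuple = (20.0, 15.0, 12.0)   # mm
    modes: dict = field(default_factory=lambda: {"y20": 0.06, "y22": 0.02})
    noise_sigma: float = 0.0                 # mm
    K: int = 10
    seed: int = 0
    spacing: tuple = (1.0, 1.0, 1.0)         # mm/voxel
    dims: tuple = (64, 64, 64)
    subdivisions: int = 3                    # icosphere level of the gt mesh


def make_ellipsoid_volume(semi_axes, spacing=(1.0, 1.0, 1.0), dims=(64, 64, 64),
                          center=None) -> LabelVolume:
    """Digitized ellipsoid: voxel = 1 iff its center is inside.

    The ellipsoid must fit inside ``dims`` with at least one background
    voxel of margin on every side.
    """
    semi_axes = np.asarray(semi_axes, dtype=np.float64)
    if np.any(semi_axes <= 0):
        raise ValueError(f"semi-axes must be positive, got {tuple(semi_axes)}")
    spacing = np.asarray(np.broadcast_to(spacing, 3), dtype=np.float64)
    dims = tuple(int(d) for d in dims)
    if center is None:
        center = (np.asarray(dims) - 1) * spacing / 2.0
    center = np.asarray(center, dtype=np.float64)
    vol = _digitize_radial(lambda u: np.ones(u.shape[:-1]), semi_axes,
                           spacing, dims, center)
    if vol.foreground_touches_border():
        raise ValueError("ellipsoid touches the volume border; enlarge dims")
    return vol


def _digitize_radial(rho, semi_axes, spacing, dims, center) -> LabelVolume:
    """Binary volume of the surface ``||p ⊘ a|| = rho(unit(p ⊘ a))``."""
    ax = [np.arange(d) * s for d, s in zip(dims, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1) - center
    scaled = P / semi_axes
    rad = np.linalg.norm(scaled, axis=-1)
    with np.errstate(invalid="ignore"):
        u = scaled / np.where(rad[..., None] > 0, rad[..., None], 1.0)
    inside = rad <= rho(u)
    # world origin at voxel (0,0,0): world = index * spacing, center in mm
    return LabelVolume(inside.astype(np.uint8), tuple(spacing), (0.0, 0.0, 0.0))


def make_shape_family(spec: ShapeFamilySpec):
    """Generate ``K`` volumes plus ground truth.

    Returns ``(volumes, gt_meshes, coeffs)``: binary volumes, corresponding
    ground-truth triangle meshes (shared icosphere connectivity, exact
    landmark correspondence, optional seeded jitter), and the true mode
    coefficients ``(K, n_modes)``.  Samples whose radial scale would pinch
    (min rho < 0.3) or overflow the volume margin are rejected and redrawn
    (logged).
    """
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(spec.semi_axes, dtype=np.float64)
    spacing = np.asarray(np.broadcast_to(spec.spacing, 3), dtype=np.float64)
    dims = np.asarray(spec.dims, dtype=np.int64)
    center = (dims - 1) * spacing / 2.0
    patterns = [MODE_PATTERNS[name] for name in spec.modes]
    sigmas = np.asarray([spec.modes[name] for name in spec.modes])

    base = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    dirs = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    psi_mesh = np.stack([p(dirs) for p in patterns], axis=1) if patterns else \
        np.zeros((len(dirs), 0))

    margin = spacing  # >= 1 voxel of background on every side
    max_rho_allowed = float(np.min(((dims - 1) * spacing / 2.0 - margin) / a))

    volumes, meshes, coeffs = [], [], []
    for k in range(spec.K):
        for attempt in range(100):
            b = rng.normal(0.0, 1.0, size=len(patterns)) * sigmas
            def rho(u, b=b):
                if not patterns:
                    return np.ones(u.shape[:-1])
                return 1.0 + sum(bk * p(u) for bk, p in zip(b, patterns))
            rho_mesh = 1.0 + psi_mesh @ b
            if rho_mesh.min() < 0.3 or rho_mesh.max() > max_rho_allowed:
                logger.info("sample %d attempt %d rejected (rho range %.2f..%.2f)",
                            k, attempt, rho_mesh.min(), rho_mesh.max())
                continue
            break
        else:
            raise RuntimeError("could not draw a valid family sample; "
                               "reduce mode amplitudes")
        vol = _digitize_radial(rho, a, spacing, tuple(int(d) for d in dims),
                               center)
        verts = rho_mesh[:, None] * (dirs * a) + center
        if spec.noise_sigma > 0:
            verts = verts + rng.normal(0.0, spec.noise_sigma, size=verts.shape)
        meshes.append(trimesh.Trimesh(vertices=verts, faces=base.faces.copy(),
                                      process=False))
        volumes.append(vol)
        coeffs.append(b)
    return volumes, meshes, np.asarray(coeffs)


def family_surface_distance(points: np.ndarray, semi_axes, center,
                            mode_names=(), b=()) -> np.ndarray:
    """Radial distance (mm) from points to a family member's surface.

    The family surfaces are radial graphs in the axis-scaled space
    ``q = (p - center) ⊘ a``: the surface is ``|q| = rho(q/|q|)``.  The
    radial gap ``(|q| - rho) `` scaled back by ``||a ⊙ q_hat||`` is the mm
    distance along the radial direction — an upper bound on (and for smooth
    low-amplitude modes a close approximation of) the true surface distance.
    """
    a = np.asarray(semi_axes, dtype=np.float64)
    q = (np.asarray(points, dtype=np.float64) - np.asarray(center)) / a
    rad = np.linalg.norm(q, axis=-1)
    u = q / np.where(rad[..., None] > 0, rad[..., None], 1.0)
    rho = 1.0 + sum(bk * MODE_PATTERNS[name](u)
                    for name, bk in zip(mode_names, b))
    return np.abs(rad - rho) * np.linalg.norm(u * a, axis=-1)


def make_point_source_edge_map(dims, location) -> EdgeMap:
    """All-zero edge map with a single unit voxel (for convolution oracles)."""
    dims = tuple(int(d) for d in dims)
    loc = tuple(int(i) for i in location)
    if any(i < 0 or i >= d for i, d in zip(loc, dims)):
        raise ValueError(f"location {loc} outside dims {dims}")
    data = np.zeros(dims)
    data[loc] = 1.0
    return EdgeMap(data)
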