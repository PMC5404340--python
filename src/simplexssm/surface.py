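"""From binary volumes to simplex meshes.

Each training sample enters the pipeline as a binary label volume and leaves
this module as a 2-simplex mesh: isosurface extraction (marching cubes, in
world mm), low-pass Taubin smoothing (no shrinkage), edge-collapse decimation
to fix the landmark count, and dualization.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from ._decimate import quadric_decimate
from .errors import NonManifoldMeshError
from .mesh import SimplexMesh, dual_simplex_from_triangles
from .volume import LabelVolume

__all__ = ["extract_surface", "smooth_mesh", "decimate_mesh", "simplex_from_volume"]


def extract_surface(vol: LabelVolume, level: float = 0.5) -> trimesh.Trimesh:
    """Closed triangle isosurface of a binary volume, in mm.

    The volume is zero-padded by one voxel before extraction so the surface
    is guaranteed closed.  Foreground voxels on the volume border are
    rejected: crop or pad the input first so the object has background margin.
    """
    data = np.asarray(vol.data)
    if not data.any():
        raise ValueError("volume has no foreground voxels")
    if vol.foreground_touches_border():
        raise ValueError(
            "foreground touches the volume border; pad the volume with "
            "background (e.g. LabelVolume.padded()) before extraction")
    padded = vol.padded(1)
    verts, faces, _, _ = measure.marching_cubes(
        padded.data.astype(np.float32), level=level, spacing=vol.spacing)
    verts = verts + np.asarray(padded.origin)
    tri = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    tri.process(validate=True)
    if tri.volume < 0:
        tri.invert()
    if not tri.is_watertight:
        raise NonManifoldMeshError("marching cubes produced an open surface")
    return tri


def smooth_mesh(tri: trimesh.Trimesh, iterations: int = 20,
                passband: float = 0.1) -> trimesh.Trimesh:
    """Low-pass (Taubin) mesh smoothing; topology unchanged, minimal shrinkage.

    Alternates a shrinking Laplacian step ``lamb`` with an inflating step
    ``mu`` chosen from the passband frequency ``k_pb`` through
    ``1/lamb + 1/mu = k_pb``.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = tri.copy()
    if iterations == 0:
        return out
    lamb = 0.5
    mu = 1.0 / (passband - 1.0 / lamb)  # negative (inflating) step
    trimesh.smoothing.filter_taubin(out, lamb=lamb, nu=-mu, iterations=iterations)
    return out


def decimate_mesh(tri: trimesh.Trimesh, target_faces: int) -> trimesh.Trimesh:
    """Reduce the face count to ``target_faces`` (exact for closed meshes)."""
    if target_faces < 4:
        raise ValueError("target_faces must be at least 4")
    if not tri.is_watertight:
        raise NonManifoldMeshError("decimation requires a closed manifold mesh")
    if len(tri.faces) <= target_faces:
        return tri.copy()
    out = quadric_decimate(tri, target_faces)
    if not out.is_watertight:
        raise NonManifoldMeshError("decimation produced a non-manifold mesh")
    return out


def simplex_from_volume(vol: LabelVolume, level: float = 0.5,
                        smooth_iterations: int = 20, passband: float = 0.1,
                        target_faces: int = 2500,
                        closing: bool = False) -> SimplexMesh:
    """Full chain: extract → smooth → decimate → dualize.

    ``closing`` applies a binary morphological closing first (hole filling
    for rough manual segmentations).  The returned simplex mesh has exactly
    one vertex per triangle of the decimated surface, i.e. ``target_faces``
    landmarks.
    """
    if closing:
        vol = LabelVolume(ndimage.binary_closing(vol.data).astype(vol.data.dtype),
                          vol.spacing, vol.origin)
    tri = extract_surface(vol, level=level)
    tri = smooth_mesh(tri, iterations=smooth_iterations, passband=passband)
    tri = decimate_mesh(tri, target_faces)
    return dual_simplex_from_triangles(tri)
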