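"""Binary label volumes with world-coordinate metadata.

Voxel index ``(i, j, k)`` (0-based, axis order x, y, z) maps to world
coordinates as ``origin + index * spacing`` (mm).  Only axis-aligned
orientations are supported; oblique affines are rejected on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["LabelVolume", "read_volume", "write_volume"]


@dataclass
class LabelVolume:
    """3-D binary grid: 0 = background, 1 = object."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    def validate_binary(self) -> None:
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"volume is not binary: values {vals[:10]}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.float64)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def padded(self, width: int = 1) -> "LabelVolume":
        """Zero-pad by ``width`` voxels on every side (origin shifts back)."""
        data = np.pad(self.data, width, mode="constant")
        origin = tuple(o - width * s for o, s in zip(self.origin, self.spacing))
        return LabelVolume(data, self.spacing, origin)

    def foreground_touches_border(self) -> bool:
        d = self.data
        return bool(d[0].any() or d[-1].any() or d[:, 0].any() or d[:, -1].any()
                    or d[:, :, 0].any() or d[:, :, -1].any())


def read_volume(path) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) volume."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
            raise ValueError(f"{path}: oblique affine not supported")
        spacing = np.abs(np.diag(aff[:3, :3]))
        origin = aff[:3, 3]
        data = np.asarray(img.dataobj)
        return LabelVolume(data, tuple(spacing), tuple(origin))
    if name.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
        return LabelVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(vol: LabelVolume, path) -> None:
    """Write NIfTI or MetaImage depending on the extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        aff = np.eye(4)
        aff[:3, :3] = np.diag(vol.spacing)
        aff[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.data), aff), str(path))
        return
    if name.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.asarray(vol.data).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path}")
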