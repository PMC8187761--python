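"""Core data container for BMD-calibrated volumes and NIfTI I/O.

Conventions used throughout the package: volumes are stored as ``(i, j, k)``
arrays with ``k`` the axial index, slice ``k = 0`` the most distal slice;
spacing is isotropic in mm; intensities are volumetric bone mineral density
in mg HA/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class CalibratedVolume:
    """A 3D BMD-calibrated image with geometric metadata.

    Parameters
    ----------
    data:
        3D float array, mg HA/cm^3.
    spacing:
        Isotropic voxel size in mm (stored per-axis; all equal for HR-pQCT).
    origin:
        Physical position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.082, 0.082, 0.082)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[0] - s[2]) < 1e-9

    @property
    def axial_extent_mm(self) -> float:
        """Physical length of the scanned section along the axial direction."""
        return self.shape[2] * self.spacing[2]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "CalibratedVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        aff = img.affine
        return cls(
            data=np.asarray(img.get_fdata(), dtype=np.float64),
            spacing=tuple(float(z) for z in zooms),
            origin=tuple(float(v) for v in aff[:3, 3]),
        )


def save_map(data: np.ndarray, like: CalibratedVolume, path) -> None:
    """Write a voxel map aligned to ``like`` as NIfTI (NaN = undefined)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), like.affine())
    img.header.set_zooms(like.spacing)
    nib.save(img, str(path))
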