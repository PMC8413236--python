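"""HU-calibrated CT volume container and NIfTI round-trip.

Arrays are indexed ``(slice, row, col)`` with slice 0 the most cranial
(cranio-caudal axial stacks). Spacing is millimetres per axis in the same
order. NIfTI stores data fastest-varying-first, so grids are transposed on
read/write; spacing travels in the header zooms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

HU_MIN = -1100.0
HU_MAX = 3000.0


@dataclass
class CTVolume:
    """A 3D Hounsfield-unit grid with voxel spacing.

    Parameters
    ----------
    hu_grid : ndarray, shape (n_slices, n_rows, n_cols)
        Attenuation in Hounsfield units; slice index 0 is most cranial.
    spacing : tuple of float
        Voxel size in mm as (axial, row, col); all components positive.
    """

    hu_grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu_grid = np.asarray(self.hu_grid, dtype=np.float32)
        if self.hu_grid.ndim != 3:
            raise ValueError("hu_grid must be 3-dimensional")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive components (mm)")
        lo, hi = float(self.hu_grid.min()), float(self.hu_grid.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU range [{lo:.0f}, {hi:.0f}] outside calibrated "
                f"[{HU_MIN:.0f}, {HU_MAX:.0f}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu_grid.shape

    def to_nifti(self, path: str) -> None:
        """Write as .nii/.nii.gz with spacing in the header zooms."""
        # (z, y, x) -> (x, y, z) for NIfTI's fastest-first layout
        data = np.transpose(self.hu_grid, (2, 1, 0)).astype(np.float32)
        affine = np.diag([self.spacing[2], self.spacing[1], self.spacing[0], 1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms((self.spacing[2], self.spacing[1], self.spacing[0]))
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "CTVolume":
        img = nib.load(path)
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        zooms = img.header.get_zooms()[:3]
        grid = np.transpose(data, (2, 1, 0))
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        return cls(hu_grid=grid, spacing=spacing)


def save_mask_nifti(mask: np.ndarray, spacing: tuple[float, float, float], path: str) -> None:
    """Write an integer label grid with the same geometry convention as CTVolume."""
    data = np.transpose(np.asarray(mask, dtype=np.int16), (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)


def load_mask_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    data = np.asarray(img.get_fdata()).astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    return np.transpose(data, (2, 1, 0)), (float(zooms[2]), float(zooms[1]), float(zooms[0]))
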