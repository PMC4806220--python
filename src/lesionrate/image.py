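"""Minimal 3-D volume container with NIfTI round-trip.

All maps exchanged between pipeline stages are :class:`VolumeImage` objects:
a scalar (or, for vector fields, component-stacked) grid with an isotropic
voxel size in millimetres and a world affine.  Grids are assumed axis-aligned;
anisotropic or oblique acquisitions are resampled upstream (out of scope
here — the phantom generates isotropic data directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full-width-at-half-maximum to a standard deviation."""
    return float(fwhm) / np.sqrt(8.0 * np.log(2.0))


def smooth_gaussian(data: np.ndarray, fwhm_mm: float, voxel_size: float) -> np.ndarray:
    """Gaussian-smooth ``data`` with a kernel of ``fwhm_mm`` millimetres."""
    if fwhm_mm <= 0:
        return np.asarray(data, dtype=float).copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma_vox)


def _default_affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


@dataclass
class VolumeImage:
    """A 3-D scalar grid with voxel size (mm) and world affine."""

    data: np.ndarray
    voxel_size: float = 1.0
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.voxel_size) ** 3

    def like(self, data: np.ndarray) -> "VolumeImage":
        """New image on this grid holding ``data``."""
        return VolumeImage(np.asarray(data), self.voxel_size, self.affine.copy())

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homo.T).T[:, :3]

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms((self.voxel_size,) * 3)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.get_fdata()), float(zooms[0]), np.asarray(img.affine))


def check_same_grid(*images: VolumeImage) -> None:
    """Raise ``ValueError`` unless all images share shape, voxel size and affine."""
    ref = images[0]
    for im in images[1:]:
        if im.shape != ref.shape:
            raise ValueError(f"grid shape mismatch: {im.shape} vs {ref.shape}")
        if not np.isclose(im.voxel_size, ref.voxel_size):
            raise ValueError("voxel size mismatch")
        if not np.allclose(im.affine, ref.affine, atol=1e-6):
            raise ValueError("affine mismatch")
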