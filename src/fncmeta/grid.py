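"""Voxel grid and brain mask on which all maps live.

A :class:`BrainGrid` couples an array shape, a voxel->mm affine and a boolean
mask. Study maps, pooled maps and statistic maps are stored as flat vectors
over the in-mask voxels; the grid converts between that representation, full
3-D volumes and NIfTI files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import DomainError

__all__ = ["BrainGrid", "make_ellipsoid_grid"]


@dataclass
class BrainGrid:
    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> MNI mm
    mask: np.ndarray  # boolean, shape == self.shape
    _coords_mm: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise DomainError("affine must be an invertible 4x4 matrix")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise DomainError("mask shape does not match grid shape")
        if not self.mask.any():
            raise DomainError("mask is empty")

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def coords_mm(self) -> np.ndarray:
        """(V, 3) mm coordinates of in-mask voxel centers, C-order over mask."""
        if self._coords_mm is None:
            ijk = np.column_stack(np.nonzero(self.mask))
            self._coords_mm = nib.affines.apply_affine(self.affine, ijk)
        return self._coords_mm

    def mm_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return nib.affines.apply_affine(inv, np.atleast_2d(np.asarray(xyz_mm, float)))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        return nib.affines.apply_affine(self.affine, np.atleast_2d(np.asarray(ijk, float)))

    def embed(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a flat in-mask vector back into a full 3-D volume."""
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.mask] = flat
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        return np.asarray(volume)[self.mask]

    def to_nifti(self, flat_or_volume: np.ndarray) -> nib.Nifti1Image:
        vol = flat_or_volume
        if vol.ndim == 1:
            vol = self.embed(vol)
        return nib.Nifti1Image(np.asarray(vol, dtype=np.float32), self.affine)

    def save_mask(self, path) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(path))

    @classmethod
    def from_nifti_mask(cls, path) -> "BrainGrid":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return cls(shape=data.shape, affine=img.affine, mask=data > 0)


def make_ellipsoid_grid(
    shape: tuple[int, int, int] = (40, 48, 40),
    voxel_size: float = 4.0,
    semiaxes_frac: tuple[float, float, float] = (0.45, 0.45, 0.45),
) -> BrainGrid:
    """MNI-like box with an ellipsoidal mask, centred at the origin.

    The default 40 x 48 x 40 box at 4 mm spans roughly the MNI bounding box;
    the ellipsoid stands in for a gray-matter template in synthetic analyses.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    # centre the grid on (0, 0, 0) mm
    affine[:3, 3] = -voxel_size * (np.array(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centre = (np.array(shape) - 1) / 2.0
    semi = np.maximum(np.array(semiaxes_frac) * np.array(shape), 1.0)
    mask = (
        ((ii - centre[0]) / semi[0]) ** 2
        + ((jj - centre[1]) / semi[1]) ** 2
        + ((kk - centre[2]) / semi[2]) ** 2
    ) <= 1.0
    return BrainGrid(shape=shape, affine=affine, mask=mask)
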