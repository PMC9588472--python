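"""Voxel grids: mask, voxel-center coordinates, NIfTI affine.

Coordinates are in millimetres with the origin at the grid center and
0-based voxel indices; the same affine is written into every NIfTI
produced by the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import FormatError, ValidationError

# MNI bounding box (~182 x 218 x 182 mm) downsampled to 8 mm isotropic voxels
MNI_8MM_SHAPE = (23, 27, 23)


@dataclass(frozen=True)
class BrainGrid:
    """A 3-D voxel grid with a binary inclusion mask.

    Attributes
    ----------
    shape : tuple of int
        Voxels per axis.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    mask : ndarray of bool, shape `shape`
        In-brain voxels.
    coords : ndarray, shape (V, 3)
        Centers of the in-mask voxels in mm (origin at the grid center).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: float
    mask: np.ndarray
    coords: np.ndarray = field(repr=False)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size_mm
        return aff

    def embed(self, values: np.ndarray) -> np.ndarray:
        """Scatter a length-V vector (or stack of them) into the 3-D volume."""
        values = np.asarray(values)
        vol = np.zeros(values.shape[:-1] + self.shape, dtype=values.dtype)
        vol[..., self.mask] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Gather in-mask values from a volume (trailing 3 axes = grid)."""
        return np.asarray(volume)[..., self.mask]


def _voxel_centers(shape, voxel_size_mm) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return (idx - (np.asarray(shape) - 1) / 2.0) * voxel_size_mm


def make_brain_grid(
    shape: tuple[int, int, int] = MNI_8MM_SHAPE,
    voxel_size_mm: float = 8.0,
    mask_source: str = "procedural_ellipsoid",
) -> BrainGrid:
    """Build a :class:`BrainGrid`.

    ``mask_source`` is either the literal ``"procedural_ellipsoid"`` — an
    axis-aligned ellipsoid inscribed at 90% of each half-extent, so the
    package needs no external template — or a path to a binary 3-D NIfTI
    mask (its shape overrides `shape`).

    A degenerate all-singleton shape yields a single voxel at the origin.
    """
    if mask_source != "procedural_ellipsoid":
        try:
            img = nib.load(str(mask_source))
        except Exception as exc:  # unreadable path / not NIfTI
            raise FormatError(f"cannot read NIfTI mask {mask_source!r}: {exc}") from exc
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError("mask NIfTI must be 3-D")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError("mask NIfTI must be binary (0/1)")
        mask = data.astype(bool)
        shape = mask.shape
        vox = float(voxel_size_mm)
    else:
        shape = tuple(int(s) for s in shape)
        if len(shape) != 3:
            raise ValidationError("shape must be a triple")
        if any(s < 1 for s in shape):
            raise ValidationError("shape components must be positive")
        if shape != (1, 1, 1) and any(s < 4 for s in shape):
            raise ValidationError("shape components must be >= 4 (or (1,1,1))")
        vox = float(voxel_size_mm)
        if vox <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        half = (np.asarray(shape) - 1) / 2.0 * vox  # half-extent in mm
        semi = np.where(half > 0, 0.9 * half, vox / 2.0)  # ellipsoid semi-axes
        centers = _voxel_centers(shape, vox)
        inside = ((centers / semi) ** 2).sum(axis=1) <= 1.0
        mask = inside.reshape(shape)

    if vox <= 0:
        raise ValidationError("voxel_size_mm must be positive")
    coords = _voxel_centers(shape, vox)[mask.reshape(-1)]
    return BrainGrid(shape=tuple(shape), voxel_size_mm=vox, mask=mask, coords=coords)
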