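"""Voxel-grid container and NIfTI adapters.

All geometry in this package lives on a regular, possibly anisotropic grid:
world coordinates are ``index * spacing + origin`` with spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume", "read_volume", "read_mask", "write_volume"]


@dataclass
class VoxelVolume:
    """A 3-D scalar or binary volume with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    def as_bool(self) -> np.ndarray:
        if not self.is_binary():
            raise ValueError("mask must be binary")
        return self.data.astype(bool)

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm coordinates."""
        return np.asarray(indices, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def like(self, data: np.ndarray) -> "VoxelVolume":
        """A new volume with this grid geometry and different data."""
        if data.shape != self.shape:
            raise ValueError("data shape does not match grid")
        return VoxelVolume(data, self.spacing, self.origin)


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError("voxel spacing missing or invalid in NIfTI header")
    return tuple(float(s) for s in spacing)


def read_volume(path: str) -> VoxelVolume:
    """Read a NIfTI volume; spacing comes from the affine, never assumed."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    affine = img.affine
    if affine is None:
        raise ValueError("NIfTI file has no affine; voxel spacing unknown")
    spacing = _spacing_from_affine(affine)
    origin = tuple(float(x) for x in affine[:3, 3])
    return VoxelVolume(data, spacing, origin)


def read_mask(path: str) -> VoxelVolume:
    """Read a NIfTI binary mask, rejecting non-binary data."""
    vol = read_volume(path)
    values = np.unique(vol.data)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("mask must be binary")
    return vol.like(vol.data.astype(np.uint8))


def write_volume(vol: VoxelVolume, path: str) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), path)
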