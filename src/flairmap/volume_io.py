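"""NIfTI volume input/output and grid geometry.

Every other module consumes the in-memory :class:`Volume` / :class:`BinaryMask`
containers defined here; files are read exactly once at the pipeline boundary.
Coordinates follow the neuroimaging convention: 0-based voxel indices, and
world coordinates in millimetres obtained through the 4x4 affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "write_mask",
    "voxel_volume_mm3",
]


def _validate_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class Volume:
    """A 3-D scalar image with its voxel->world geometry.

    Parameters
    ----------
    data
        3-D floating point array of intensities (arbitrary units).
    affine
        4x4 matrix mapping 0-based voxel indices to world millimetres.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D input: data has {self.data.ndim} dimensions")
        self.affine = _validate_affine(self.affine)
        if any(d <= 0 or not np.isfinite(d) for d in self.voxel_dims):
            raise ValueError(f"voxel dimensions must be positive and finite: {self.voxel_dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        """Voxel edge lengths (dx, dy, dz) in mm (column norms of the affine)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return float(dx * dy * dz)

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to (n, 3) world mm."""
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        return indices @ self.affine[:3, :3].T + self.affine[:3, 3]

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on the same grid with different data."""
        return Volume(data=data, affine=self.affine.copy())


@dataclass
class BinaryMask:
    """A boolean grid sharing the geometry of its parent :class:`Volume`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D input: mask has {self.data.ndim} dimensions")
        self.affine = _validate_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))  # type: ignore[return-value]

    def n_voxels(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return float(self.data.sum() * dx * dy * dz)

    def check_same_grid(self, other) -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")


def read_volume(path, nan: str = "raise") -> Volume:
    """Load a NIfTI-1/NIfTI-2 file (optionally gzipped) as a :class:`Volume`.

    4-D images are accepted only when the trailing dimensions are singletons,
    which are squeezed away. ``nan`` controls NaN handling: ``"raise"`` errors
    on any NaN, ``"zero"`` replaces NaNs by 0 (appropriate only when the NaNs
    are known to lie outside the brain).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D input: {path} has shape {data.shape}")
    if np.isnan(data).any():
        if nan == "zero":
            data = np.nan_to_num(data, nan=0.0)
        else:
            raise ValueError(f"NaN values in {path}; pass nan='zero' to blank them")
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float))


def write_volume(v: Volume, path, dtype=np.float32) -> None:
    """Write a Volume as NIfTI-1. Intensities are stored as 32-bit float."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(v.data.astype(dtype), v.affine)
    nib.save(img, str(path))


def write_mask(m: BinaryMask, path) -> None:
    """Write a BinaryMask as NIfTI-1 with unsigned 8-bit storage."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(m.data.astype(np.uint8), m.affine)
    nib.save(img, str(path))


def voxel_volume_mm3(v: Volume) -> float:
    """Volume of one voxel in mm^3 (dx * dy * dz)."""
    return v.voxel_volume_mm3()
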