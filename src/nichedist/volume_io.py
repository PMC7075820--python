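"""Template-space volume I/O and coordinate conventions.

All volumes live on a single 3D grid with a voxel-index -> world-mm affine
(RAS+ millimetres, 0-based indices). Distances everywhere in the package are
measured between voxel *centers* in world space, so the affine — not the
voxel spacing alone — defines geometry. NIfTI-1 is the on-disk format; the
header affine is authoritative (nibabel's sform-over-qform precedence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LabeledVolume",
    "BinaryMask",
    "VolumeError",
    "MaskFileNotFoundError",
    "NotThreeDimensionalError",
    "SingularAffineError",
    "GridMismatchError",
    "read_mask",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "same_grid",
]


class VolumeError(ValueError):
    """Base class for volume validation failures."""


class MaskFileNotFoundError(VolumeError, FileNotFoundError):
    """The requested volume file does not exist."""


class NotThreeDimensionalError(VolumeError):
    """The volume does not have exactly three spatial axes."""


class SingularAffineError(VolumeError):
    """The voxel-to-world affine is not invertible."""


class GridMismatchError(VolumeError):
    """Two volumes that must share a grid have different shapes or affines."""


def _validate_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise VolumeError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise SingularAffineError("voxel-to-world affine is singular")
    return affine


@dataclass
class LabeledVolume:
    """A 3D scalar grid (counts or labels) with its voxel->world-mm affine.

    ``spacing`` is derived: the Euclidean column norms of the affine's linear
    part, i.e. the world-space step per unit voxel index along each axis.
    """

    data: np.ndarray
    affine: np.ndarray
    spacing: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotThreeDimensionalError(
                f"volume must be 3D, got {self.data.ndim} axes"
            )
        self.affine = _validate_affine(self.affine)
        self.spacing = np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel cell = |det| of the linear part."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class BinaryMask(LabeledVolume):
    """A LabeledVolume whose data is restricted to {0, 1} (uint8)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype == bool:
            self.data = self.data.astype(np.uint8)
        elif self.data.size:
            lo, hi = self.data.min(), self.data.max()
            if lo < 0 or hi > 1 or not np.all(self.data == self.data.astype(np.uint8)):
                raise VolumeError("binary mask may only contain 0 and 1")
            self.data = self.data.astype(np.uint8)
        else:
            self.data = self.data.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())

    def foreground_indices(self) -> np.ndarray:
        """(N, 3) integer indices of foreground voxels."""
        return np.argwhere(self.data > 0)

    def foreground_world(self) -> np.ndarray:
        """(N, 3) world-mm coordinates of foreground voxel centers."""
        idx = self.foreground_indices()
        return apply_affine(self.affine, idx)


def apply_affine(affine: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Map (N, 3) voxel indices through a 4x4 affine to (N, 3) world mm."""
    indices = np.atleast_2d(np.asarray(indices, dtype=float))
    return indices @ affine[:3, :3].T + affine[:3, 3]


def read_volume(path: str | Path) -> LabeledVolume:
    """Read any 3D NIfTI volume without binarization."""
    path = Path(path)
    if not path.exists():
        raise MaskFileNotFoundError(f"volume file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and data.shape[3:] == (1,) * (data.ndim - 3) else data
    return LabeledVolume(data=data, affine=img.affine)


def read_mask(path: str | Path, binarize_threshold: float = 0.5) -> BinaryMask:
    """Read a NIfTI volume and binarize at ``binarize_threshold``.

    Voxels with value >= threshold become foreground. Typical input masks
    are already binary; the threshold tolerates fractional values left by
    registration resampling.
    """
    vol = read_volume(path)
    data = (np.asarray(vol.data, dtype=float) >= binarize_threshold).astype(np.uint8)
    return BinaryMask(data=data, affine=vol.affine)


def write_volume(volume: LabeledVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving integer data exactly.

    Integer-valued data is stored in the narrowest of uint8/int16/int32 that
    holds its range (a 159-subject heatmap fits int16); floats go out as
    float64 so round-trips stay bit-exact.
    """
    path = Path(path)
    if not path.parent.exists():
        raise VolumeError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(volume.data)
    if np.issubdtype(data.dtype, np.integer) or (
        np.issubdtype(data.dtype, np.floating) and np.all(data == np.round(data))
    ):
        data = data.astype(np.int64)
        lo, hi = (int(data.min()), int(data.max())) if data.size else (0, 0)
        for dt in (np.uint8, np.int16, np.int32, np.int64):
            info = np.iinfo(dt)
            if info.min <= lo and hi <= info.max:
                data = data.astype(dt)
                break
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, path)


def voxel_to_world(volume: LabeledVolume, index) -> np.ndarray:
    """World-mm coordinates of the center of voxel ``index`` (0-based)."""
    index = np.asarray(index)
    if index.shape != (3,):
        raise VolumeError(f"index must be a triple, got shape {index.shape}")
    if np.any(index < 0) or np.any(index >= np.array(volume.shape)):
        raise IndexError(f"index {tuple(index)} outside grid {volume.shape}")
    return apply_affine(volume.affine, index)[0]


def world_to_voxel(volume: LabeledVolume, point) -> np.ndarray:
    """Continuous voxel coordinates of a world-mm point (inverse affine)."""
    point = np.asarray(point, dtype=float)
    inv = np.linalg.inv(volume.affine)
    return np.atleast_2d(point) @ inv[:3, :3].T + inv[:3, 3] if point.ndim > 1 else (
        inv[:3, :3] @ point + inv[:3, 3]
    )


def same_grid(a: LabeledVolume, b: LabeledVolume, atol: float = 1e-6) -> bool:
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)


def require_same_grid(a: LabeledVolume, b: LabeledVolume, what: str = "volumes") -> None:
    if not same_grid(a, b):
        raise GridMismatchError(f"{what} do not share one grid (shape/affine differ)")
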