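"""Volume and mask data model shared by every pipeline stage.

All geometry lives in a single convention: voxel indices are 0-based, the
world frame is RAS in millimetres, and the world point of a voxel is its
centre.  Volumes are plain scalar grids with a diagonal voxel-to-world
mapping (spacing + origin); paired volumes in this pipeline always share a
grid, so no resampling machinery is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "Volume3D",
    "BinaryMask",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_from_threshold",
    "sample_mask_points",
]

MODALITIES = ("structural", "angiographic", "combined", "pet")


class VolumeFormatError(ValueError):
    """Raised for unreadable or non-3D volume files."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice with an RAS millimetre world mapping.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; each component >= 1.
    spacing : tuple of float
        Voxel edge lengths in mm; all strictly positive.
    origin : tuple of float
        World (mm) coordinate of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive mm values, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, RAS)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World-mm centres of the given (n, 3) integer voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def all_voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) world-mm centres of every voxel, C order."""
        grids = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_centers(grids)


@dataclass
class Volume3D:
    """Scalar volume over a :class:`VoxelGrid` with a modality tag."""

    grid: VoxelGrid
    values: np.ndarray
    modality: str = "structural"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    def copy(self) -> "Volume3D":
        return Volume3D(self.grid, self.values.copy(), self.modality)


@dataclass
class BinaryMask:
    """Boolean inclusion mask over a :class:`VoxelGrid`."""

    grid: VoxelGrid
    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.included.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VoxelGrid:
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = tuple(float(x) for x in affine[:3, 3])
    return VoxelGrid(shape=tuple(shape), spacing=spacing, origin=origin)


def read_volume(path: str | Path, modality: str = "structural") -> Volume3D:
    """Load a 3D NIfTI-1 volume.

    Raises
    ------
    VolumeFormatError
        If the file cannot be read or its data are not 3-dimensional.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got {data.ndim}D")
    grid = _grid_from_affine(img.affine, data.shape)
    return Volume3D(grid=grid, values=data, modality=modality)


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving values bit-exactly."""
    img = nib.Nifti1Image(volume.values, volume.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Load a mask stored as a 0/1 NIfTI volume (nonzero = included)."""
    vol = read_volume(path, modality="pet")
    return BinaryMask(grid=vol.grid, included=vol.values != 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    vol = Volume3D(mask.grid, mask.included.astype(np.uint8), modality="pet")
    write_volume(vol, path)


def mask_from_threshold(volume: Volume3D, threshold: float) -> BinaryMask:
    """Binary mask of voxels whose value strictly exceeds ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryMask(grid=volume.grid, included=volume.values > threshold)


def sample_mask_points(mask: BinaryMask, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` voxel centres uniformly (with replacement) from a mask.

    Returns an (n, 3) array of world-mm points.  Deterministic given
    ``seed``.  Raises ``ValueError`` on an empty mask or ``n < 1``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.argwhere(mask.included)
    if idx.shape[0] == 0:
        raise ValueError("cannot sample from an empty mask")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, idx.shape[0], size=n)
    return mask.grid.voxel_centers(idx[picks])
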