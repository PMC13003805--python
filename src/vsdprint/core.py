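"""Core containers: voxel grids, binary vascular volumes, intensity volumes, volume I/O.

Physical convention used throughout the package: the voxel grid is 0-indexed,
voxel centers sit at ``index * voxel_size`` micrometres (voxel-center convention),
and all lengths are in micrometres unless a name says otherwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis.
    voxel_size : float
        Edge length of a voxel in micrometres (isotropic).
    """

    shape: tuple[int, int, int]
    voxel_size: float

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid in µm."""
        return tuple(s * self.voxel_size for s in self.shape)

    def axis_centers_um(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return np.arange(self.shape[axis], dtype=float) * self.voxel_size


@dataclass
class BinaryVascularVolume:
    """Binary segmentation of vasculature on a voxel grid.

    ``meta`` records provenance (e.g. the threshold used by segmentation).
    """

    mask: np.ndarray
    grid: VoxelGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def cbv(self) -> float:
        """Blood-volume fraction: nonzero voxels over total voxels."""
        return float(self.mask.mean())


@dataclass
class IntensityVolume:
    """Grayscale 3D volume (e.g. a rendered light-sheet microscopy stack)."""

    data: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )


def write_volume(path: str, data: np.ndarray, voxel_size: float) -> None:
    """Write a 3D array as multi-page TIFF (.tif/.tiff) or NIfTI (.nii/.nii.gz)."""
    ext = _ext(path)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif ext in (".nii", ".nii.gz"):
        import nibabel as nib

        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        nib.save(nib.Nifti1Image(arr, affine), path)
    else:
        raise ValueError(f"unsupported volume format: {path}")


def read_volume(path: str, voxel_size: float | None = None) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 3D volume from TIFF or NIfTI; returns (array, grid).

    For TIFF the voxel size must be supplied; for NIfTI it is taken from the
    affine unless overridden.
    """
    ext = _ext(path)
    if ext in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
        if voxel_size is None:
            raise ValueError("voxel_size is required when reading TIFF volumes")
        vs = voxel_size
    elif ext in (".nii", ".nii.gz"):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.dataobj)
        vs = voxel_size if voxel_size is not None else float(abs(img.affine[0, 0]))
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
    return arr, VoxelGrid(arr.shape, vs)


def _ext(path: str) -> str:
    base = os.path.basename(path).lower()
    if base.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(base)[1]
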