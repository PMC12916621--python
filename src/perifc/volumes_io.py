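"""NIfTI volume and TSV motion-trace I/O with explicit grid bookkeeping.

Every object in the pipeline carries a :class:`VoxelGrid` describing its voxel
lattice (dimensions, physical voxel size in millimetres, repetition time for 4D
data, and which grid axis crosses the mid-sagittal plane).  All voxel indices
are 0-based ``(x, y, z)`` triples; frame indices are 0-based.  Images are
assumed to be already co-registered to a common, left-right grid-aligned space:
the mid-sagittal plane is the grid plane ``x = (nx - 1) / 2`` along
``left_right_axis``, so hemispheric mirroring is the index map
``x -> nx - 1 - x``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

#: tolerance (mm, per axis) when comparing voxel sizes of two grids
GRID_TOL_MM = 1e-3


class VolumeIOError(Exception):
    """Base class for I/O failures in this module."""


class NotA4DSeriesError(VolumeIOError):
    """A BOLD reader was pointed at a file that is not a 4D series."""


class BadVoxelSizeError(VolumeIOError):
    """A volume header declares a non-positive voxel dimension."""


class GridMismatchError(VolumeIOError):
    """Two volumes that must share a voxel grid do not."""


class MotionFileError(VolumeIOError):
    """A motion-parameter TSV is malformed."""


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel lattice: dimensions, physical spacing, TR, and left-right axis."""

    dims: tuple[int, int, int]
    voxel_mm: tuple[float, float, float]
    tr_s: float | None = None
    left_right_axis: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_mm", tuple(float(v) for v in self.voxel_mm))
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise BadVoxelSizeError(f"voxel sizes must be positive, got {self.voxel_mm}")
        if self.tr_s is not None and self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.left_right_axis not in (0, 1, 2):
            raise ValueError(f"left_right_axis must be 0, 1 or 2, got {self.left_right_axis}")

    def spacing_matches(self, other: "VoxelGrid", tol_mm: float = GRID_TOL_MM) -> bool:
        return self.dims == other.dims and all(
            abs(a - b) <= tol_mm for a, b in zip(self.voxel_mm, other.voxel_mm)
        )

    def require_same(self, other: "VoxelGrid", what: str = "volume") -> None:
        if not self.spacing_matches(other):
            raise GridMismatchError(
                f"grid mismatch for {what}: expected dims={self.dims} "
                f"voxel_mm={self.voxel_mm}, got dims={other.dims} voxel_mm={other.voxel_mm}"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_mm
        return dx * dy * dz

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_mm) + [1.0])
        return aff


@dataclass
class Volume3D:
    """A scalar volume on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )


@dataclass
class Volume4D:
    """A BOLD series: one scalar per voxel per frame, shape (nx, ny, nz, T)."""

    grid: VoxelGrid
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        if self.series.ndim != 4:
            raise NotA4DSeriesError(f"expected 4D data, got {self.series.ndim}D")
        if self.series.shape[:3] != self.grid.dims:
            raise ValueError(
                f"series shape {self.series.shape[:3]} does not match grid dims {self.grid.dims}"
            )
        if self.series.shape[3] < 1:
            raise ValueError("a 4D series needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.series.shape[3]


@dataclass
class BinaryMask:
    """A binary volume stored as a boolean array; set semantics on voxel indices."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )

    @classmethod
    def from_indices(cls, grid: VoxelGrid, indices) -> "BinaryMask":
        data = np.zeros(grid.dims, dtype=bool)
        for idx in indices:
            i, j, k = (int(v) for v in idx)
            if not (0 <= i < grid.dims[0] and 0 <= j < grid.dims[1] and 0 <= k < grid.dims[2]):
                raise ValueError(f"index {idx} outside grid dims {grid.dims}")
            data[i, j, k] = True
        return cls(grid, data)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """Member voxel indices as an (N, 3) int array in lexicographic order."""
        return np.argwhere(self.data)

    def members(self) -> set[tuple[int, int, int]]:
        return {tuple(int(v) for v in row) for row in self.indices()}

    def to_volume3d(self) -> Volume3D:
        return Volume3D(self.grid, self.data.astype(np.float64))


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame.

    Columns 0-2 are translations in millimetres, columns 3-5 rotations in
    degrees, following the common realignment-output convention.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise MotionFileError(
                f"motion trace must have 6 columns, got shape {self.params.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]


def _grid_from_header(img, need_time: bool) -> VoxelGrid:
    zooms = img.header.get_zooms()
    voxel_mm = tuple(float(z) for z in zooms[:3])
    if any(v <= 0 for v in voxel_mm):
        raise BadVoxelSizeError(f"non-positive voxel size in header: {voxel_mm}")
    tr_s = None
    if need_time and len(zooms) > 3 and zooms[3] > 0:
        tr_s = float(zooms[3])
    return VoxelGrid(dims=tuple(img.shape[:3]), voxel_mm=voxel_mm, tr_s=tr_s)


def read_bold(path: str | os.PathLike) -> Volume4D:
    """Read a 4D NIfTI BOLD series.

    Voxel sizes come from the header ``pixdim``; TR from the time-axis spacing.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise NotA4DSeriesError(f"{path}: not a 4D series (shape {img.shape})")
    grid = _grid_from_header(img, need_time=True)
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume4D(grid=grid, series=data)


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a 3D NIfTI scalar volume."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    shape = tuple(img.shape)
    data = np.asarray(img.dataobj, dtype=np.float64)
    # tolerate a trailing singleton time axis
    if len(shape) == 4 and shape[3] == 1:
        data = data[..., 0]
        shape = shape[:3]
    if len(shape) != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got shape {img.shape}")
    grid = _grid_from_header(img, need_time=False)
    grid = VoxelGrid(dims=shape, voxel_mm=grid.voxel_mm)
    return Volume3D(grid=grid, values=data)


def read_mask(path: str | os.PathLike, grid: VoxelGrid) -> BinaryMask:
    """Read a binary mask and check it lives on ``grid``.

    Voxels with value > 0.5 are members, which keeps behaviour defined for
    fractional values produced by upstream resampling.
    """
    vol = read_volume(path)
    if not grid.spacing_matches(vol.grid):
        raise GridMismatchError(
            f"grid mismatch reading mask {path}: expected dims={grid.dims} "
            f"voxel_mm={grid.voxel_mm}, file has dims={vol.grid.dims} "
            f"voxel_mm={vol.grid.voxel_mm}"
        )
    return BinaryMask(grid=grid, data=vol.values > 0.5)


def read_motion(path: str | os.PathLike) -> MotionTrace:
    """Read a six-column TSV of motion parameters (one row per frame).

    Lines starting with ``#`` are treated as comments.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"motion file not found: {path}")
    try:
        arr = np.loadtxt(str(path), comments="#", ndmin=2)
    except ValueError as exc:
        raise MotionFileError(f"{path}: non-numeric motion data ({exc})") from exc
    if arr.shape[1] != 6:
        raise MotionFileError(f"{path}: expected 6 columns, got {arr.shape[1]}")
    return MotionTrace(params=arr)


def write_motion(trace: MotionTrace, path: str | os.PathLike) -> None:
    np.savetxt(str(path), trace.params, delimiter="\t", fmt="%.10g")


def write_volume(vol: Volume3D | Volume4D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, float32, preserving voxel sizes (and TR for 4D)."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise VolumeIOError(f"cannot write {path}: directory {parent} does not exist")
    if isinstance(vol, Volume4D):
        data = vol.series.astype(np.float32)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, affine=vol.grid.affine())
    if isinstance(vol, Volume4D) and vol.grid.tr_s is not None:
        img.header.set_zooms(tuple(vol.grid.voxel_mm) + (vol.grid.tr_s,))
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
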