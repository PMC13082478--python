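"""Label-volume I/O, voxel geometry, and nearest-neighbor label resampling.

Axis convention: the first two voxel axes (x, y) span the axial plane;
the third axis (z) is the axial slice index.  This is enforced at load
time in the sense that all downstream in-plane measurements use axes
(0, 1) and treat axis 2 as through-plane.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True, eq=False)
class ImageGrid:
    """A 3D voxel lattice with physical geometry.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); z indexes axial slices.
    spacing
        Voxel size in mm along each axis; all components positive.
    affine
        4x4 invertible matrix mapping voxel indices (homogeneous) to
        physical mm coordinates.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        affine = np.asarray(self.affine, dtype=float)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape!r}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing!r}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is degenerate (non-invertible)")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageGrid):
            return NotImplemented
        return (self.shape == other.shape and self.spacing == other.spacing
                and np.array_equal(self.affine, other.affine))

    def __hash__(self) -> int:
        return hash((self.shape, self.spacing, self.affine.tobytes()))

    @classmethod
    def from_spacing(cls, shape: tuple[int, int, int], spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "ImageGrid":
        """Axis-aligned grid with a diagonal affine."""
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        return cls(shape=tuple(shape), spacing=tuple(spacing), affine=affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[0], self.spacing[1]

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to physical mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class LabelVolume:
    """An integer-labeled 3D mask with geometry and study metadata."""

    grid: ImageGrid
    data: np.ndarray
    study_index: int = 0
    study_date: datetime.date | None = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer-typed, got {self.data.dtype}")
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError(f"data shape {self.data.shape} != grid shape {self.grid.shape}")
        if self.data.size and int(self.data.min()) < 0:
            raise ValueError("label values must be >= 0 (0 = background)")
        if self.study_index < 0:
            raise ValueError("study_index must be nonnegative")

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.data))

    def labels(self) -> np.ndarray:
        """Sorted nonzero label values present in the volume."""
        vals = np.unique(self.data)
        return vals[vals > 0]


def read_label_volume(path: str | Path, *, study_index: int = 0,
                      study_date: datetime.date | None = None,
                      patient_id: str = "") -> LabelVolume:
    """Read a NIfTI-1 label volume.

    The header affine and zooms are passed through untouched; voxel
    values are preserved exactly.  Float-typed files are accepted only
    when every value is integral.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {img.ndim}D")
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.isfinite(data)) or not np.array_equal(data, np.round(data)):
            raise ValueError(f"{path}: voxel values are not integers; refusing to interpret as labels")
        data = np.round(data).astype(np.int32)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32, copy=False)
    else:
        raise ValueError(f"{path}: unsupported voxel dtype {data.dtype}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = ImageGrid(shape=tuple(int(s) for s in data.shape), spacing=zooms, affine=np.asarray(img.affine))
    return LabelVolume(grid=grid, data=data, study_index=study_index,
                       study_date=study_date, patient_id=patient_id)


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as NIfTI-1 (int32 voxels)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.int32), vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))
    return path


def resample_labels(vol: LabelVolume, ref: ImageGrid) -> LabelVolume:
    """Resample a label volume onto a reference grid (nearest neighbor).

    The voxel-to-voxel map is taken from the two stored affines, so
    co-registered inputs land in the same physical space.  Labels are
    categorical: no interpolation, and the output label set is always a
    subset of the input label set.
    """
    try:
        mapping = np.linalg.inv(vol.grid.affine) @ ref.affine
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate affine; cannot resample") from exc
    out = ndimage.affine_transform(
        vol.data,
        matrix=mapping[:3, :3],
        offset=mapping[:3, 3],
        output_shape=ref.shape,
        order=0,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    return LabelVolume(grid=ref, data=out.astype(np.int32), study_index=vol.study_index,
                       study_date=vol.study_date, patient_id=vol.patient_id)
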