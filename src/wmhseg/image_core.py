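"""Volumetric image model, NIfTI-1 I/O, affine resampling and mask algebra.

Every image in this package is a :class:`Volume`: a 3-D float32 intensity
grid together with a 4x4 voxel-index -> world-mm affine. Binary masks are
Volumes whose data is constrained to {0, 1}. World-to-world affine maps
(e.g. produced by registration) are :class:`AffineTransform` objects and are
applied by pull-back resampling onto a target grid.

Conventions: voxel indices are 0-based; the affine maps homogeneous index
``(i, j, k, 1)`` to world mm (NIfTI-1 practice); out-of-field voxels are
filled with 0 on resampling, because downstream intensity statistics treat
exact zeros as background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "BinaryMask",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "resample",
    "apply_mask",
    "voxel_volume_mm3",
    "read_transform",
    "write_transform",
]


class FormatError(ValueError):
    """Raised for files that are not valid 3-D NIfTI-1 images."""


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class Volume:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    data:
        3-D array of intensities; cast to float32 and checked for NaN/Inf.
    affine:
        4x4 voxel-index -> world-mm matrix; its upper-left 3x3 block must
        be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D array, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains NaN or Inf")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0.0:
            raise ValueError("affine 3x3 block is singular")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume", atol: float = 1e-4) -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def copy(self) -> "Volume":
        return type(self)(self.data.copy(), self.affine.copy())


class BinaryMask(Volume):
    """A Volume whose voxels are exactly 0 or 1."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("mask voxels must be exactly 0 or 1")

    @classmethod
    def from_bool(cls, arr: np.ndarray, affine: np.ndarray) -> "BinaryMask":
        return cls(np.asarray(arr, dtype=bool).astype(np.float32), affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def complement(self) -> "BinaryMask":
        return BinaryMask(1.0 - self.data, self.affine.copy())


@dataclass
class AffineTransform:
    """World-mm to world-mm affine map (moving space -> fixed space)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise np.linalg.LinAlgError("singular affine transform")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t: np.ndarray | tuple[float, float, float]) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self applied after ``other`` (self @ other)."""
        return AffineTransform(self.matrix @ other.matrix)

    def apply_to_points(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def _pick_affine(img: nib.Nifti1Image) -> np.ndarray:
    """sform when its code > 0, else qform, else spacing-only diagonal."""
    hdr = img.header
    sform, scode = img.get_sform(coded=True)
    if scode and scode > 0:
        logger.debug("using sform affine (code %d)", scode)
        return sform
    qform, qcode = img.get_qform(coded=True)
    if qcode and qcode > 0:
        logger.debug("using qform affine (code %d)", qcode)
        return qform
    zooms = hdr.get_zooms()[:3]
    logger.debug("no coded sform/qform; falling back to spacing-only affine")
    return np.diag(list(zooms) + [1.0])


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 image (.nii or .nii.gz) as a float32 Volume.

    Trailing singleton dimensions (e.g. a 4-D file with last dim 1) are
    squeezed; any other dimensionality is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path.name}: expected a 3-D image, header declares {data.ndim} dimensions"
        )
    return Volume(np.nan_to_num(data.astype(np.float32)), _pick_affine(img))


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 with its affine stored as both sform and qform."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.set_sform(vol.affine, code=2)
    img.set_qform(vol.affine, code=2)
    nib.save(img, str(path))


def resample(
    moving: Volume,
    transform: AffineTransform,
    target: Volume,
    interpolation: str = "trilinear",
) -> Volume:
    """Resample ``moving`` onto ``target``'s grid under a world-space affine.

    Each target voxel is pulled back through ``inv(moving.affine) @
    inv(transform) @ target.affine`` and the moving image is sampled there;
    voxels mapping outside the moving field of view are 0. Nearest
    interpolation on a :class:`BinaryMask` returns a :class:`BinaryMask`.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 0 if interpolation == "nearest" else 1
    # index_target -> index_moving map for scipy's pull-back convention
    m = np.linalg.inv(moving.affine) @ np.linalg.inv(transform.matrix) @ target.affine
    out = ndimage.affine_transform(
        moving.data,
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.grid_shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    out = np.asarray(out, dtype=np.float32)
    if isinstance(moving, BinaryMask) and interpolation == "nearest":
        return BinaryMask(out, target.affine.copy())
    return Volume(out, target.affine.copy())


def apply_mask(vol: Volume, mask: BinaryMask) -> Volume:
    """Voxelwise product; voxels outside the mask become exactly 0."""
    if not vol.same_grid(mask):
        raise GridMismatchError(
            f"volume grid {vol.grid_shape} does not match mask grid {mask.grid_shape}"
        )
    return type(vol)(vol.data * mask.data, vol.affine.copy())


def voxel_volume_mm3(vol: Volume) -> float:
    """Volume of one voxel in mm^3: |det| of the affine's 3x3 block."""
    return float(abs(np.linalg.det(vol.affine[:3, :3])))


def read_transform(path: str | Path) -> AffineTransform:
    """Read a FLIRT-style 4-line whitespace-separated 4x4 matrix."""
    mat = np.loadtxt(path)
    return AffineTransform(mat)


def write_transform(t: AffineTransform, path: str | Path) -> None:
    np.savetxt(path, t.matrix, fmt="%.10g")
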