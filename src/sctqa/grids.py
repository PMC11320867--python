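"""Geometry-aware voxel data model and mask algebra.

Every mask and HU volume in this package is bound to an :class:`ImageGrid`:
an axis-aligned anisotropic voxel lattice described by its spacing (mm), the
world coordinate of the *center* of voxel ``(0, 0, 0)`` (mm) and its shape.
Array axes are ``(x, y, z)`` with ``z`` the axial (slice) direction; voxel
indices are 0-based. A ``frame_id`` labels the frame of reference: grids in
the same frame may be resampled into one another, grids in different frames
require registration, which this package deliberately does not perform.

Boolean mask operations (:func:`intersect`, :func:`subtract`, :func:`union`)
require *compatible* grids — identical spacing, origin, shape and frame.
Cross-grid comparisons within one frame go through :func:`resample_to_grid`,
which uses nearest-neighbour assignment by world position of the target
voxel centers so masks stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import (
    GridMismatchError,
    RegistrationRequiredError,
    ValidationError,
)

Modality = Literal["CT", "sCT", "CBCT", "MR", "derived"]

#: Relative tolerance for comparing grid metadata (spacing/origin survive a
#: float64 NIfTI round trip well below this).
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned voxel lattice in physical (mm) coordinates.

    Parameters
    ----------
    spacing
        Voxel size per axis in mm; all components must be positive.
    origin
        World coordinate (mm) of the center of voxel index ``(0, 0, 0)``.
    shape
        Number of voxels per axis; all components must be at least 1.
    frame_id
        Opaque frame-of-reference label. Grids can only be resampled into
        one another when their frames match.
    """

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    frame_id: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or len(self.origin) != 3 or len(self.shape) != 3:
            raise ValidationError("grids are three-dimensional")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValidationError(f"shape components must be >= 1, got {self.shape}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal_mm(self) -> float:
        """Length of the main diagonal of one voxel, in mm."""
        return float(np.linalg.norm(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def compatible(self, other: "ImageGrid") -> bool:
        """True iff spacing, origin, shape and frame all agree."""
        return (
            self.frame_id == other.frame_id
            and self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=_GRID_RTOL, atol=0.0)
            and np.allclose(self.origin, other.origin, rtol=_GRID_RTOL, atol=1e-6)
        )

    def require_compatible(self, other: "ImageGrid") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                self.frame_id,
                other.frame_id,
                f"spacing {self.spacing} vs {other.spacing}, "
                f"shape {self.shape} vs {other.shape}",
            )


@dataclass
class BinaryStructure:
    """A named binary voxel mask bound to a grid.

    ``name`` is the structure's role (``CTV``, ``PTV_a``, ``brain``,
    ``bone``, ``artefact`` ...); free-form roles use the ``other:<label>``
    convention. Emptiness is representable: an all-false mask is valid.
    """

    name: str
    modality: Modality
    grid: ImageGrid
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match grid shape "
                f"{self.grid.shape} for structure {self.name!r}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def volume_cc(self) -> float:
        """Mask volume in cubic centimetres (voxel count x voxel volume)."""
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    def with_mask(self, mask: np.ndarray, name: str | None = None) -> "BinaryStructure":
        return BinaryStructure(
            name=name if name is not None else self.name,
            modality=self.modality,
            grid=self.grid,
            mask=mask,
        )


@dataclass
class HUVolume:
    """A Hounsfield-unit valued image on a grid."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)
    modality: Modality = "CT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"values shape {self.values.shape} does not match grid shape "
                f"{self.grid.shape}"
            )


def _binary_op(a: BinaryStructure, b: BinaryStructure, mask: np.ndarray) -> BinaryStructure:
    return BinaryStructure(name="derived", modality="derived", grid=a.grid, mask=mask)


def intersect(a: BinaryStructure, b: BinaryStructure) -> BinaryStructure:
    """Voxelwise AND of two masks on one grid."""
    a.grid.require_compatible(b.grid)
    return _binary_op(a, b, a.mask & b.mask)


def subtract(a: BinaryStructure, b: BinaryStructure) -> BinaryStructure:
    """Voxelwise ``a AND NOT b`` on one grid."""
    a.grid.require_compatible(b.grid)
    return _binary_op(a, b, a.mask & ~b.mask)


def union(a: BinaryStructure, b: BinaryStructure) -> BinaryStructure:
    """Voxelwise OR of two masks on one grid."""
    a.grid.require_compatible(b.grid)
    return _binary_op(a, b, a.mask | b.mask)


def resample_to_grid(s: BinaryStructure, target: ImageGrid) -> BinaryStructure:
    """Resample a mask onto another grid in the same frame of reference.

    Each target voxel takes the value of the source voxel whose center is
    nearest to the target voxel's center (per-axis rounding, valid because
    both grids are axis-aligned). Target voxels whose centers fall outside
    the source extent are false. Masks stay strictly binary; no
    interpolation is ever applied.
    """
    if s.grid.frame_id != target.frame_id:
        raise RegistrationRequiredError(
            f"cannot resample across frames {s.grid.frame_id!r} -> "
            f"{target.frame_id!r}; inputs must be co-registered upstream"
        )
    if s.grid.compatible(target):
        return BinaryStructure(s.name, s.modality, target, s.mask.copy())

    index_lists = []
    valid_lists = []
    for axis in range(3):
        world = target.axis_coords(axis)
        idx = np.rint((world - s.grid.origin[axis]) / s.grid.spacing[axis]).astype(int)
        valid = (idx >= 0) & (idx < s.grid.shape[axis])
        index_lists.append(np.clip(idx, 0, s.grid.shape[axis] - 1))
        valid_lists.append(valid)

    ix, iy, iz = np.ix_(*index_lists)
    out = s.mask[ix, iy, iz]
    vx, vy, vz = valid_lists
    out &= vx[:, None, None] & vy[None, :, None] & vz[None, None, :]
    return BinaryStructure(s.name, s.modality, target, out)


def shifted_grid(grid: ImageGrid, shift_mm: tuple[float, float, float]) -> ImageGrid:
    """Grid translated rigidly by ``shift_mm`` (same frame)."""
    origin = tuple(o + d for o, d in zip(grid.origin, shift_mm))
    return replace(grid, origin=origin)
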