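"""Voxel-grid containers and the physical-coordinate contract.

All grids live on a regular lattice in LPS (DICOM patient) coordinates:
the center of voxel ``(i, j, k)`` sits at ``origin + direction @ (spacing * [i, j, k])``
with ``spacing`` in mm/voxel.  Arrays are indexed ``values[i, j, k]`` with axis
order matching the columns of the direction matrix, i.e. index axis 0 runs
along the first physical direction column.  Voxel indexing is 0-based and
boxes are half-open ``[lower, upper)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Union

import numpy as np
import SimpleITK as sitk

from .errors import BoundsError, GeometryError, ValidationError

# Segment roles used throughout the pipeline.
ROLE_BACKGROUND = "background"
ROLE_METAPHYSIS = "metaphysis"
ROLE_EPIPHYSIS = "epiphysis_center"
ROLE_FUSION = "fusion_area"
KNOWN_ROLES = (ROLE_BACKGROUND, ROLE_METAPHYSIS, ROLE_EPIPHYSIS, ROLE_FUSION)


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise GeometryError(f"{name} must be a 3-vector, got shape {np.shape(x)}")
    return v


def _check_direction(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float).reshape(3, 3)
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
        raise GeometryError("direction matrix is not orthonormal")
    if abs(abs(np.linalg.det(d)) - 1.0) > 1e-6:
        raise GeometryError("direction matrix determinant is not ±1")
    return d


@dataclass
class _Grid:
    """Shared lattice geometry for scalar, label and mask grids."""

    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.direction = _check_direction(self.direction)

    @property
    def shape(self):
        return self._array().shape

    def _array(self) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError

    def index_to_physical(self, index) -> np.ndarray:
        """Physical mm coordinates of voxel center(s); index may be (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of physical point(s) (..., 3)."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.direction) / self.spacing

    def same_lattice(self, other: "_Grid", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def require_same_lattice(self, other: "_Grid", what: str = "grids"):
        if not self.same_lattice(other):
            raise GeometryError(f"{what} are not on the same lattice")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))


@dataclass
class ScalarVolume(_Grid):
    """A 3-D scalar grid in Hounsfield units with its physical placement."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1)))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")

    def _array(self):
        return self.values


@dataclass
class LabelGrid(_Grid):
    """Integer label grid on a ScalarVolume lattice.

    Label 0 is background; every nonzero label present in the array must
    appear in ``legend`` mapping label id -> anatomical role.
    """

    labels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.int32))
    legend: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from legend")

    def _array(self):
        return self.labels

    def labels_for_role(self, role: str) -> list:
        return sorted(l for l, r in self.legend.items() if r == role)

    def support(self, label_ids) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        ids = np.atleast_1d(np.asarray(list(label_ids) if not np.isscalar(label_ids) else [label_ids]))
        return np.isin(self.labels, ids)

    def count(self, label_ids) -> int:
        return int(self.support(label_ids).sum())

    def with_labels(self, labels: np.ndarray, legend: Optional[Dict[int, str]] = None) -> "LabelGrid":
        return LabelGrid(
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            direction=self.direction.copy(),
            labels=labels,
            legend=dict(self.legend if legend is None else legend),
        )


@dataclass
class BinaryMask(_Grid):
    """Boolean occupancy grid on a ScalarVolume lattice."""

    mask: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=bool))

    def __post_init__(self):
        super().__post_init__()
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError("mask must be a 3-D array")

    def _array(self):
        return self.mask


@dataclass(frozen=True)
class RoiBox:
    """Half-open voxel-index box [lower, upper), 0-based."""

    lower: tuple
    upper: tuple

    def __post_init__(self):
        lo = tuple(int(x) for x in self.lower)
        up = tuple(int(x) for x in self.upper)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if len(lo) != 3 or len(up) != 3:
            raise BoundsError("RoiBox lower/upper must be 3-vectors")
        if not all(l < u for l, u in zip(lo, up)):
            raise BoundsError(f"RoiBox is empty or inverted: lower={lo}, upper={up}")

    def validate_for(self, grid: _Grid):
        shape = grid.shape
        if any(l < 0 for l in self.lower) or any(u > s for u, s in zip(self.upper, shape)):
            raise BoundsError(f"RoiBox {self.lower}..{self.upper} outside grid of shape {shape}")

    @staticmethod
    def from_physical(grid: _Grid, lower_mm, upper_mm) -> "RoiBox":
        """Build a voxel box from two physical corner points (mm).

        Corners are mapped to continuous indices, sorted per axis and
        rounded outward so the physical box is fully covered, then clipped
        to the grid.
        """
        a = grid.physical_to_index(_as_vec3(lower_mm, "lower_mm"))
        b = grid.physical_to_index(_as_vec3(upper_mm, "upper_mm"))
        lo = np.floor(np.minimum(a, b) + 0.5).astype(int)
        up = np.ceil(np.maximum(a, b) + 0.5).astype(int)
        lo = np.clip(lo, 0, np.asarray(grid.shape) - 1)
        up = np.clip(up, 1, np.asarray(grid.shape))
        return RoiBox(tuple(lo), tuple(up))


GridLike = Union[ScalarVolume, LabelGrid, BinaryMask]


def crop_roi(vol: GridLike, box: RoiBox) -> GridLike:
    """Extract the sub-grid inside ``box``; values are copied bit-identically.

    The origin shifts by ``direction @ (lower * spacing)`` so physical voxel
    positions are preserved.
    """
    box.validate_for(vol)
    sl = tuple(slice(l, u) for l, u in zip(box.lower, box.upper))
    new_origin = vol.index_to_physical(np.asarray(box.lower, dtype=float))
    common = dict(spacing=vol.spacing.copy(), origin=new_origin, direction=vol.direction.copy())
    if isinstance(vol, ScalarVolume):
        return ScalarVolume(values=vol.values[sl].copy(), meta=dict(vol.meta), **common)
    if isinstance(vol, LabelGrid):
        return LabelGrid(labels=vol.labels[sl].copy(), legend=dict(vol.legend), **common)
    return BinaryMask(mask=vol.mask[sl].copy(), **common)


def _to_sitk(grid: GridLike) -> sitk.Image:
    arr = grid._array()
    if isinstance(grid, ScalarVolume):
        arr = np.asarray(arr, dtype=np.float32)
    elif isinstance(grid, BinaryMask):
        arr = np.asarray(arr, dtype=np.uint8)
    else:
        arr = np.asarray(arr, dtype=np.int32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    img.SetDirection(tuple(float(d) for d in grid.direction.flatten()))
    return img


def _from_sitk(img: sitk.Image, like: GridLike, legend=None) -> GridLike:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.array(img.GetSpacing())
    origin = np.array(img.GetOrigin())
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if isinstance(like, ScalarVolume):
        return ScalarVolume(spacing=spacing, origin=origin, direction=direction,
                            values=np.asarray(arr, dtype=float), meta=dict(like.meta))
    if isinstance(like, BinaryMask):
        return BinaryMask(spacing=spacing, origin=origin, direction=direction,
                          mask=arr.astype(bool))
    return LabelGrid(spacing=spacing, origin=origin, direction=direction,
                     labels=arr.astype(np.int32),
                     legend=dict(like.legend if legend is None else legend))


def resample_isotropic(grid: GridLike, target_spacing: float) -> GridLike:
    """Resample onto an isotropic lattice at ``target_spacing`` mm.

    Scalar volumes are interpolated linearly, label grids and masks by
    nearest neighbour (so no label can be invented).  The physical extent
    is preserved to within one voxel; the first voxel center is kept fixed.
    """
    if target_spacing <= 0:
        raise GeometryError("target_spacing must be positive")
    target_spacing = float(target_spacing)
    old_shape = np.asarray(grid.shape, dtype=float)
    new_shape = np.maximum(1, np.round(old_shape * grid.spacing / target_spacing)).astype(int)
    if np.allclose(grid.spacing, target_spacing) and np.array_equal(new_shape, grid.shape):
        return crop_roi(grid, RoiBox((0, 0, 0), tuple(grid.shape)))  # copy

    img = _to_sitk(grid)
    scalar = isinstance(grid, ScalarVolume)
    interp = sitk.sitkLinear if scalar else sitk.sitkNearestNeighbor
    default = float(np.min(grid.values)) if scalar else 0.0
    out = sitk.Resample(
        img,
        [int(n) for n in new_shape],
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target_spacing,) * 3,
        img.GetDirection(),
        default,
        img.GetPixelID(),
    )
    return _from_sitk(out, grid)
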