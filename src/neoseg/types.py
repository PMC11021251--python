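"""Core in-memory containers shared by every stage of the pipeline.

A :class:`Volume` is a 3-D scalar grid with per-axis voxel spacing in mm and
an optional NIfTI affine.  Axis order is fixed as (x: left-right,
y: posterior-anterior, z: inferior-superior).  A :class:`LabelVolume` is an
integer grid with the same geometry plus a code -> structure-name table.
Brain masks are plain boolean arrays paired with a geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class NeosegError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NeosegError, ValueError):
    """A precondition on an operation argument was violated."""


class DegenerateInputError(NeosegError, ValueError):
    """Input is valid in shape but degenerate in content (e.g. constant
    intensities passed to a clustering that needs distinct values)."""


class DegenerateResultError(NeosegError, RuntimeError):
    """An operation produced an unusable result (e.g. a brain mask that
    collapsed to empty after morphological opening)."""


class StageDependencyError(NeosegError, RuntimeError):
    """A pipeline stage is missing a prerequisite output file."""


def _check_geometry(shape, spacing) -> tuple[float, float, float]:
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise InvalidArgumentError(f"expected a 3-D grid, got shape {shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InvalidArgumentError(f"spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass
class Volume:
    """3-D scalar image with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = _check_geometry(self.data.shape, self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new voxel data."""
        if data.shape != self.data.shape:
            raise InvalidArgumentError(
                f"data shape {data.shape} does not match volume shape {self.data.shape}"
            )
        return replace(self, data=data)

    def same_geometry(self, other: "Volume | LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class LabelVolume:
    """3-D non-negative integer label grid with a code -> name table."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    table: dict[int, str] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InvalidArgumentError("label data must be an integer array")
        if self.data.min(initial=0) < 0:
            raise InvalidArgumentError("label codes must be non-negative")
        self.spacing = _check_geometry(self.data.shape, self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def codes(self) -> np.ndarray:
        """Sorted nonzero codes present in the grid."""
        c = np.unique(self.data)
        return c[c > 0]

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given codes."""
        return np.isin(self.data, list(codes))

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        if data.shape != self.data.shape:
            raise InvalidArgumentError(
                f"data shape {data.shape} does not match volume shape {self.data.shape}"
            )
        return replace(self, data=np.asarray(data, dtype=self.data.dtype))

    def same_geometry(self, other: "Volume | LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def as_mask(a: np.ndarray) -> np.ndarray:
    """Coerce to a boolean mask array."""
    return np.asarray(a).astype(bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a = as_mask(a)
    b = as_mask(b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom
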