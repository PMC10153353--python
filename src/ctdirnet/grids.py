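"""Core in-memory containers: CT volumes, displacement fields, structure sets, dose grids.

All grids use the (z, y, x) axis convention with 0-based voxel indices; spacing is
reported as (dz, dy, dx) in millimetres.  Displacement fields are stored in voxel
units on the same grid as the volume they deform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, DimensionalityError, ParameterError

Triple = tuple[float, float, float]


def _check_grid(values: np.ndarray, spacing, what: str) -> None:
    if values.ndim != 3:
        raise DimensionalityError(f"{what} must be 3-D, got {values.ndim}-D")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ParameterError(f"{what} spacing must be 3 positive numbers, got {spacing}")
    if not np.all(np.isfinite(values)):
        raise ParameterError(f"{what} contains non-finite values")


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield-unit values with voxel spacing metadata."""

    values: np.ndarray                      # (nz, ny, nx), HU
    spacing: Triple                         # (dz, dy, dx) mm
    origin: Triple = (0.0, 0.0, 0.0)        # (z, y, x) mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.values, self.spacing, "CTVolume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class NormVolume:
    """A normalized (unitless, nominally ~[0, 1]) intensity volume.

    Produced by :func:`ctdirnet.io_preprocess.normalize`; values are not clipped,
    so HU above the normalization scale map above 1.
    """

    values: np.ndarray
    spacing: Triple
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.values, self.spacing, "NormVolume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class DisplacementField:
    """Per-voxel 3-component displacement in voxel units, order (z, y, x).

    ``components[c]`` holds the displacement along axis ``c`` for every voxel of
    the grid it registers; backward-warping samples the moving image at
    ``p + g(p)``.
    """

    components: np.ndarray                  # (3, nz, ny, nx), voxel units
    spacing: Triple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.ndim != 4 or self.components.shape[0] != 3:
            raise DimensionalityError(
                f"DisplacementField needs shape (3, nz, ny, nx), got {self.components.shape}"
            )
        if not np.all(np.isfinite(self.components)):
            raise ParameterError("DisplacementField contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[1:]

    def max_magnitude(self) -> float:
        """Largest Euclidean displacement norm over the grid, in voxels."""
        return float(np.sqrt((self.components ** 2).sum(axis=0)).max())


@dataclass
class StructureSet:
    """Named binary bitmaps (CTV + organs at risk) on a shared grid."""

    masks: dict[str, np.ndarray]
    spacing: Triple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, mask in self.masks.items():
            arr = np.asarray(mask).astype(bool)
            if arr.ndim != 3:
                raise DimensionalityError(f"structure {name!r} must be 3-D")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ConsistencyError(
                    f"structure {name!r} shape {arr.shape} differs from {shape}"
                )
            clean[name] = arr
        self.masks = clean
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def names(self) -> list[str]:
        return list(self.masks.keys())

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)


@dataclass
class DoseGrid:
    """A 3-D grid of absorbed dose (Gy) with voxel spacing metadata."""

    values: np.ndarray                      # (nz, ny, nx), Gy
    spacing: Triple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_grid(self.values, self.spacing, "DoseGrid")
        if np.any(self.values < 0):
            raise ParameterError("DoseGrid contains negative dose")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def require_same_grid(a, b, what: str = "inputs") -> None:
    """Raise ConsistencyError unless two grid objects share shape."""
    if a.shape != b.shape:
        raise ConsistencyError(f"{what} live on different grids: {a.shape} vs {b.shape}")
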