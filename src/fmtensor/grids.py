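"""Voxel-grid containers with physical (micrometre) geometry.

Arrays are indexed ``[i, j, k]`` in X, Y, Z order.  The physical coordinate
of voxel ``(i, j, k)`` is ``origin + index * spacing`` (voxel-centre
convention, 0-based indices).  Every public API in the package speaks
physical µm XYZ; the array index order is an internal detail fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["VoxelGrid", "BinaryMask", "LabelVolume"]

#: 26-connectivity structuring element shared by the whole package.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelGrid:
    """A 3D scalar grid with voxel spacing and origin in µm.

    Parameters
    ----------
    data:
        3D array, axis order ``(x, y, z)``.
    spacing:
        Voxel pitch ``(sx, sy, sz)`` in µm, strictly positive.
    origin:
        Physical coordinate of voxel ``(0, 0, 0)`` in µm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in np.ravel(self.spacing))
        self.origin = tuple(float(o) for o in np.ravel(self.origin))
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 or not np.isfinite(s) for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical µm coordinate of (fractional) voxel indices ``(..., 3)``."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel index of physical coordinates ``(..., 3)``."""
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def center_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) physical coordinates of the first/last voxel centres."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) physical extent of the voxel volume (±half a voxel)."""
        lo, hi = self.center_bounds
        half = 0.5 * np.asarray(self.spacing)
        return lo - half, hi + half


@dataclass
class BinaryMask(VoxelGrid):
    """A :class:`VoxelGrid` whose values are exactly 0 or 1 (stored uint8)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.data
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("binary mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume(VoxelGrid):
    """A :class:`VoxelGrid` of nonnegative integer labels; 0 is background."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be nonnegative")

    def labels(self) -> np.ndarray:
        """Sorted nonzero label values present in the volume."""
        u = np.unique(self.data)
        return u[u != 0]

    def check_connected(self) -> bool:
        """True if every label forms one 26-connected component (on-demand check)."""
        for lab in self.labels():
            _, n = ndimage.label(self.data == lab, structure=STRUCT_26)
            if n != 1:
                return False
        return True
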