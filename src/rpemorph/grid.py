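"""Voxel containers shared by every pipeline stage.

Arrays follow the microscopy stack convention ``(z, y, x)`` (pages, rows,
columns) while the physical spacing is given per *named* axis as
``(sx, sy, sz)`` in micrometres — the order in which acquisition software
reports pixel size. Voxel centres sit at ``index * spacing`` along each axis
(0-based, half-open voxel convention); all public measurements are in
physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import SpacingError

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)  # type: ignore[assignment]
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise SpacingError(f"spacing must be three positive floats (sx, sy, sz), got {spacing!r}")
    return spacing  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """A 3D scalar image with anisotropic physical spacing.

    Parameters
    ----------
    values
        ``(nz, ny, nx)`` array of finite, non-negative intensities.
    spacing
        Voxel pitch ``(sx, sy, sz)`` in µm.
    time
        Acquisition time in hours post fertilization (hpf), if part of a series.
    channel
        Free-text channel label (e.g. ``"tissue"``, ``"nuclei"``).
    """

    values: np.ndarray
    spacing: Spacing
    time: Optional[float] = None
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array (z, y, x), got ndim={self.values.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinates ``(x, y, z)`` along each axis, µm."""
        nz, ny, nx = self.values.shape
        sx, sy, sz = self.spacing
        return np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """Copy of this grid carrying new values; geometry/metadata preserved."""
        if values.shape != self.values.shape:
            raise ValueError(f"shape changed {self.values.shape} -> {values.shape}")
        return replace(self, values=values)

    def same_geometry(self, other: "VoxelGrid | SegmentationMask") -> bool:
        return self.values.shape == other.values.shape and self.spacing == other.spacing


@dataclass
class SegmentationMask:
    """Binary foreground sharing a :class:`VoxelGrid`'s geometry."""

    values: np.ndarray
    spacing: Spacing
    time: Optional[float] = None
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array (z, y, x), got ndim={self.values.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nz, ny, nx = self.values.shape
        sx, sy, sz = self.spacing
        return np.arange(nx) * sx, np.arange(ny) * sy, np.arange(nz) * sz

    def foreground_coords(self) -> np.ndarray:
        """``(n, 3)`` physical coordinates ``(x, y, z)`` of foreground voxel centres."""
        zz, yy, xx = np.nonzero(self.values)
        sx, sy, sz = self.spacing
        return np.column_stack([xx * sx, yy * sy, zz * sz])

    def same_geometry(self, other: "VoxelGrid | SegmentationMask") -> bool:
        return self.values.shape == other.values.shape and self.spacing == other.spacing
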