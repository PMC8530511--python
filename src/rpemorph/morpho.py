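"""Tissue-scale morphometrics: volume, surface, thickness, blocks, hull.

The operational definitions follow the classic voxel-count morphometry of
time-lapse organogenesis data:

* **volume** — number of foreground voxels times the physical voxel volume;
* **surface** — graph area of a full quadratic surface ``x = f(y, z)`` fitted
  by least squares to the foreground voxel centres (the y-z plane is the
  plane of the optic-cup hinges, so the epithelial sheet is single-valued
  in x);
* **thickness** — volume / surface, the mean thickness of a curved sheet;
* **blocks** — the anterior-posterior extent of the z-projected foreground is
  split into equal-width intervals so rim-contaminated (CMZ) blocks can be
  excluded from tissue metrics at late stages;
* **convex hull volume** — whole-eye volume including the lens cavity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError, GeometryError
from .grid import SegmentationMask, VoxelGrid


# ---------------------------------------------------------------------------
# volume and thickness
# ---------------------------------------------------------------------------

def voxel_volume(mask: SegmentationMask) -> float:
    """Foreground voxel count times the voxel volume, in µm³."""
    return float(np.count_nonzero(mask.values)) * mask.voxel_volume_um3


def thickness(volume: float, surface: float) -> float:
    """Mean sheet thickness, volume (µm³) / surface (µm²), in µm."""
    if surface <= 0:
        raise ZeroDivisionError(f"surface must be positive to define thickness, got {surface}")
    return volume / surface


# ---------------------------------------------------------------------------
# quadratic surface fit
# ---------------------------------------------------------------------------

@dataclass
class SurfaceFit:
    """Least-squares quadratic ``x = f(y, z)`` over the mask's voxel centres.

    Coefficients are in centred coordinates ``u = y - y0``, ``v = z - z0``:
    ``x = c0 + c1 u + c2 v + c3 u² + c4 u v + c5 v²``.
    """

    coeffs: np.ndarray  # (6,)
    y0: float
    z0: float
    footprint: np.ndarray  # (nz, ny) bool — columns used for the area integral
    residual_rms: float  # µm

    def evaluate(self, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        u, v = np.asarray(y) - self.y0, np.asarray(z) - self.z0
        c = self.coeffs
        return c[0] + c[1] * u + c[2] * v + c[3] * u * u + c[4] * u * v + c[5] * v * v

    def gradients(self, y: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(∂x/∂y, ∂x/∂z) at the given physical coordinates."""
        u, v = np.asarray(y) - self.y0, np.asarray(z) - self.z0
        c = self.coeffs
        return c[1] + 2 * c[3] * u + c[4] * v, c[2] + c[4] * u + 2 * c[5] * v


def fit_surface(
    mask: SegmentationMask,
    trim_partial_columns: bool = True,
) -> tuple[SurfaceFit, float]:
    """Fit the sheet's mid-surface and integrate its graph area, in µm².

    The area is ``Σ sy·sz·sqrt(1 + (∂x/∂y)² + (∂x/∂z)²)`` over the (y, z)
    columns of the projected foreground. With ``trim_partial_columns`` (the
    default) columns whose x-extent is below half the median column extent are
    dropped from the integration footprint: those are rim cut-face columns
    that only graze the sheet, and keeping them inflates the footprint from
    the mid-surface out to the outer shell radius (a ~(1 + t/2R)² area excess
    for a shell of thickness t and radius R). The fit itself always uses every
    foreground voxel.

    Raises :class:`DegenerateGeometryError` when the foreground cannot support
    a full quadratic (rank-deficient design, e.g. collinear columns).
    """
    fg = mask.values
    n_fg = int(np.count_nonzero(fg))
    if n_fg < 6:
        raise DegenerateGeometryError(f"need at least 6 foreground voxels, got {n_fg}")
    sx, sy, sz = mask.spacing
    zz, yy, xx = np.nonzero(fg)
    x = xx * sx
    y = yy * sy
    z = zz * sz
    if np.unique(yy).size < 2 or np.unique(zz).size < 2:
        raise DegenerateGeometryError("foreground must span at least 2 distinct y and z values")

    y0, z0 = float(y.mean()), float(z.mean())
    u, v = y - y0, z - z0
    design = np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])
    coeffs, _, rank, _ = np.linalg.lstsq(design, x, rcond=None)
    if rank < 6:
        raise DegenerateGeometryError(
            f"rank-deficient quadratic fit (rank {rank} < 6): degenerate footprint"
        )
    resid = x - design @ coeffs
    fit = SurfaceFit(
        coeffs=coeffs,
        y0=y0,
        z0=z0,
        footprint=fg.any(axis=2),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )

    counts = fg.sum(axis=2)  # x-extent per (z, y) column, in voxels
    footprint = counts > 0
    if trim_partial_columns:
        med = np.median(counts[footprint])
        footprint = counts >= max(1.0, 0.5 * med)
    fit.footprint = footprint

    iz, iy = np.nonzero(footprint)
    gy, gz = fit.gradients(iy * sy, iz * sz)
    area = float(np.sum(np.sqrt(1.0 + gy**2 + gz**2)) * sy * sz)
    return fit, area


# ---------------------------------------------------------------------------
# block discretization and CMZ exclusion
# ---------------------------------------------------------------------------

@dataclass
class BlockPartition:
    """Equal-width x-intervals over the z-projected foreground bounding range.

    Block 1 sits at the lowest x; ``anterior`` states which end of the x axis
    is the anatomical anterior (where the proliferative rim arises), and
    ``excluded_anterior`` how many anterior-most blocks are dropped from
    tissue metrics.
    """

    n_blocks: int
    edges_um: np.ndarray  # (n_blocks + 1,) physical x bounds
    anterior: Literal["+x", "-x"] = "+x"
    excluded_anterior: int = 0

    def __post_init__(self) -> None:
        if self.excluded_anterior not in (0, 1, 2):
            raise GeometryError(f"excluded anterior block count must be 0, 1 or 2, got {self.excluded_anterior}")

    def retained_blocks(self) -> list[int]:
        """1-based ids of blocks that survive the CMZ exclusion."""
        ids = list(range(1, self.n_blocks + 1))
        if self.excluded_anterior == 0:
            return ids
        if self.anterior == "+x":
            return ids[: self.n_blocks - self.excluded_anterior]
        return ids[self.excluded_anterior:]


def discretize_blocks(
    mask: SegmentationMask,
    n_blocks: int = 7,
    anterior: Literal["+x", "-x"] = "+x",
) -> tuple[BlockPartition, list[SegmentationMask]]:
    """Split the foreground into ``n_blocks`` equal-width x-intervals.

    The anterior-posterior extent of the z-projected foreground bounding box
    is divided into equal-width intervals; each voxel is assigned by the x
    coordinate of its centre (left-closed bins, last bin closed). Block
    volumes therefore sum exactly to the whole-tissue volume.
    """
    if n_blocks < 1:
        raise GeometryError("n_blocks must be >= 1")
    fg = mask.values
    if not fg.any():
        raise GeometryError("cannot discretize an empty mask")
    sx, _, _ = mask.spacing
    x_any = fg.any(axis=(0, 1))  # occupancy per x column of the z-projection
    ix = np.nonzero(x_any)[0]
    ix_min, ix_max = int(ix[0]), int(ix[-1])
    if int(np.count_nonzero(x_any)) < n_blocks:
        raise GeometryError(
            f"only {int(np.count_nonzero(x_any))} distinct x columns for {n_blocks} blocks"
        )
    span = ix_max - ix_min
    edges = ix_min * sx + (span * sx) * np.arange(n_blocks + 1) / n_blocks

    # integer bin assignment: exact, no floating-point boundary ambiguity
    all_ix = np.arange(fg.shape[2])
    rel = (all_ix - ix_min) * n_blocks
    block_of_column = np.minimum(rel // span if span > 0 else np.zeros_like(rel), n_blocks - 1)
    block_of_column = np.clip(block_of_column, 0, n_blocks - 1)

    partition = BlockPartition(n_blocks=n_blocks, edges_um=edges, anterior=anterior)
    blocks: list[SegmentationMask] = []
    for b in range(n_blocks):
        sel = block_of_column == b
        sub = fg & sel[None, None, :]
        blocks.append(SegmentationMask(sub, mask.spacing, time=mask.time, channel=mask.channel))
    return partition, blocks


def exclude_cmz_blocks(
    partition: BlockPartition,
    time: float,
    t_one: float = 20.0,
    t_two: Optional[float] = None,
) -> BlockPartition:
    """Drop rim-contaminated anterior blocks as the CMZ reporter arises.

    Frames before ``t_one`` (hpf) keep all blocks; the frame at ``t_one``
    drops the single most anterior block; frames after ``t_one`` (or from
    ``t_two`` on, when given) drop the two most anterior blocks.
    """
    if t_two is not None and t_two <= t_one:
        raise GeometryError("t_two must come after t_one")
    if time < t_one - 1e-9:
        k = 0
    elif math.isclose(time, t_one, abs_tol=1e-9) or (t_two is not None and time < t_two - 1e-9):
        k = 1
    else:
        k = 2
    return replace(partition, excluded_anterior=k)


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------

def convex_hull_volume(grid: VoxelGrid | SegmentationMask) -> float:
    """Volume (µm³) of the 3D convex hull of the foreground voxel region.

    Foreground is every voxel with a value greater than zero. The hull is
    taken over the voxels' cube corners (each voxel occupies
    ``(i ± 1/2)·spacing`` per axis), so the hull of a solid box equals the
    box volume exactly and the hull volume is never below the voxel volume of
    the same mask. Only boundary voxels feed the hull for speed. Degenerate
    (coplanar) masks raise :class:`DegenerateGeometryError`.
    """
    fg = grid.values > 0 if isinstance(grid, VoxelGrid) else grid.values
    n_fg = int(np.count_nonzero(fg))
    if n_fg < 1:
        raise DegenerateGeometryError("empty mask has no convex hull")
    from scipy import ndimage  # local import keeps module deps flat

    boundary = fg & ~ndimage.binary_erosion(fg)
    zz, yy, xx = np.nonzero(boundary)
    sx, sy, sz = grid.spacing
    # a 3D tissue needs >= 4 non-coplanar voxels; flat point sets are degenerate
    centres = np.column_stack([xx * sx, yy * sy, zz * sz])
    if n_fg < 4 or np.linalg.matrix_rank(centres - centres.mean(axis=0)) < 3:
        raise DegenerateGeometryError(
            "foreground must contain at least 4 non-coplanar voxels for a 3D hull"
        )
    corners = []
    for dz in (-0.5, 0.5):
        for dy in (-0.5, 0.5):
            for dx in (-0.5, 0.5):
                corners.append(
                    np.column_stack([(xx + dx) * sx, (yy + dy) * sy, (zz + dz) * sz])
                )
    pts = np.concatenate(corners)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set for convex hull: {exc}") from exc
    return float(hull.volume)


# ---------------------------------------------------------------------------
# per-frame metrics assembly
# ---------------------------------------------------------------------------

@dataclass
class TissueMetrics:
    """One row of the per-frame, per-block metrics table (block 0 = whole tissue)."""

    time_hpf: float
    block: int
    volume_um3: float
    surface_um2: float
    thickness_um: float


def measure_mask(
    mask: SegmentationMask,
    block: int = 0,
    trim_partial_columns: bool = True,
) -> TissueMetrics:
    """Volume, fitted surface and V/S thickness for one mask."""
    vol = voxel_volume(mask)
    _, surf = fit_surface(mask, trim_partial_columns=trim_partial_columns)
    return TissueMetrics(
        time_hpf=mask.time if mask.time is not None else float("nan"),
        block=block,
        volume_um3=vol,
        surface_um2=surf,
        thickness_um=thickness(vol, surf),
    )
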