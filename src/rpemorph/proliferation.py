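"""Proliferation indices: labelled-nucleus fractions per region and species.

The proliferation index of an epithelium is the percentage of nuclei positive
for an S-phase/cycling marker (BrdU, Ki67) among all nuclei inside a region of
interest. Two routes are provided: counting from known nucleus centres (the
phantom-truth or manually-clicked route) and counting from the image channels
themselves (threshold, close, connected components, overlap with the marker
channel). A cross-species summary table relates the index to mean apico-basal
cell length, where flatter epithelia proliferate less.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from scipy.stats import spearmanr

from .errors import EmptyRegionError
from .grid import SegmentationMask, VoxelGrid
from .preprocess import close_nuclei


@dataclass
class ProliferationSummary:
    """Labelled-cell count for one (species, stage, region) combination."""

    n_total: int
    n_positive: int
    species: Optional[str] = None
    stage: Optional[str] = None
    region: Optional[str] = None
    mean_ab_length_um: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError(
                f"need 0 <= n_positive <= n_total, got {self.n_positive}/{self.n_total}"
            )

    @property
    def percent_positive(self) -> float:
        if self.n_total == 0:
            raise EmptyRegionError("percentage undefined: no nuclei in region")
        return 100.0 * self.n_positive / self.n_total


def count_positive_fraction(
    total_centres: np.ndarray,
    positive_flags: np.ndarray,
    region_mask: SegmentationMask,
    **labels: str,
) -> ProliferationSummary:
    """Count labelled vs total nucleus centres falling inside a region mask.

    ``total_centres`` is ``(n, 3)`` physical ``(x, y, z)`` µm; a centre is
    in-region when the voxel containing it is foreground. Raises
    :class:`EmptyRegionError` when no centre falls inside the region.
    """
    centres = np.asarray(total_centres, dtype=float)
    flags = np.asarray(positive_flags, dtype=bool)
    if centres.ndim != 2 or centres.shape[1] != 3 or flags.shape != (centres.shape[0],):
        raise ValueError("centres must be (n, 3) with one flag per centre")
    sx, sy, sz = region_mask.spacing
    nz, ny, nx = region_mask.shape
    ix = np.round(centres[:, 0] / sx).astype(int)
    iy = np.round(centres[:, 1] / sy).astype(int)
    iz = np.round(centres[:, 2] / sz).astype(int)
    inside_image = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    in_region = np.zeros(centres.shape[0], dtype=bool)
    in_region[inside_image] = region_mask.values[iz[inside_image], iy[inside_image], ix[inside_image]]
    n_total = int(in_region.sum())
    if n_total == 0:
        raise EmptyRegionError("no nucleus centres inside the region mask")
    n_pos = int((flags & in_region).sum())
    return ProliferationSummary(n_total=n_total, n_positive=n_pos, **labels)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _otsu_mask(grid: VoxelGrid) -> np.ndarray:
    values = grid.values
    if not np.any(values > 0):
        return np.zeros_like(values, dtype=bool)
    if values.min() == values.max():
        return values > 0
    return values > threshold_otsu(values)


def segment_and_count(
    total_channel: VoxelGrid,
    positive_channel: VoxelGrid,
    region_mask: Optional[SegmentationMask] = None,
    closing_radius: int = 1,
    overlap_fraction: float = 0.5,
    **labels: str,
) -> ProliferationSummary:
    """Detect nuclei as connected components and score marker positivity.

    Both channels are Otsu-thresholded after a grey-scale closing
    (``closing_radius`` voxels in-plane; small by default so distinct nuclei
    are not bridged); nuclei are 26-connected components of the total channel
    whose centroid voxel lies in ``region_mask`` (whole image when omitted).
    A nucleus is positive when at least ``overlap_fraction`` of its voxels are
    foreground in the positive channel.
    """
    if not total_channel.same_geometry(positive_channel):
        raise ValueError("total and positive channels must share geometry")
    if not np.any(total_channel.values > 0):
        raise EmptyRegionError("total nuclei channel is empty")
    total = _otsu_mask(close_nuclei(total_channel, se_radius=closing_radius))
    positive = _otsu_mask(close_nuclei(positive_channel, se_radius=closing_radius))

    lab, n_comp = ndimage.label(total, structure=_CONN26)
    if n_comp == 0:
        raise EmptyRegionError("no nuclei detected in the total channel")

    comp_ids = np.arange(1, n_comp + 1)
    if region_mask is not None:
        if not region_mask.same_geometry(total_channel):
            raise ValueError("region mask must share the channels' geometry")
        centroids = ndimage.center_of_mass(total, lab, comp_ids)
        keep = []
        nz, ny, nx = region_mask.shape
        for cid, (cz, cy, cx) in zip(comp_ids, centroids):
            iz, iy, ix = (int(round(cz)), int(round(cy)), int(round(cx)))
            if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx and region_mask.values[iz, iy, ix]:
                keep.append(cid)
        comp_ids = np.asarray(keep, dtype=int)
    if comp_ids.size == 0:
        raise EmptyRegionError("no detected nuclei inside the region mask")

    sizes = ndimage.sum_labels(np.ones_like(lab), lab, comp_ids)
    pos_overlap = ndimage.sum_labels(positive.astype(float), lab, comp_ids)
    n_pos = int(np.count_nonzero(pos_overlap / sizes >= overlap_fraction))
    return ProliferationSummary(n_total=int(comp_ids.size), n_positive=n_pos, **labels)


@dataclass
class ProliferationCorrelation:
    """Tidy cross-species table plus the rank correlation of % positive vs A-B length."""

    table: pd.DataFrame
    rho: float
    p_value: float
    defined: bool = True


def proliferation_vs_thickness_table(
    summaries: Sequence[ProliferationSummary],
) -> ProliferationCorrelation:
    """Spearman rank correlation between proliferation index and A-B length.

    Needs at least 3 rows carrying both a percentage and a mean apico-basal
    length. A constant column leaves the correlation undefined
    (``defined=False``, ``rho`` NaN) rather than raising.
    """
    rows = [s for s in summaries if s.mean_ab_length_um is not None]
    if len(rows) < 3:
        raise ValueError(f"need at least 3 summaries with A-B lengths, got {len(rows)}")
    table = pd.DataFrame(
        {
            "species": [s.species for s in rows],
            "stage": [s.stage for s in rows],
            "region": [s.region for s in rows],
            "n_total": [s.n_total for s in rows],
            "n_positive": [s.n_positive for s in rows],
            "percent_positive": [s.percent_positive for s in rows],
            "mean_ab_length_um": [s.mean_ab_length_um for s in rows],
        }
    )
    pct = table["percent_positive"].to_numpy()
    ab = table["mean_ab_length_um"].to_numpy(dtype=float)
    if np.ptp(pct) == 0 or np.ptp(ab) == 0:
        return ProliferationCorrelation(table=table, rho=float("nan"), p_value=float("nan"), defined=False)
    rho, p = spearmanr(pct, ab)
    return ProliferationCorrelation(table=table, rho=float(rho), p_value=float(p), defined=True)
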