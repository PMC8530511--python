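"""Reading and writing stacks, masks and ground-truth sidecars.

Images travel as multi-page TIFF (one page per z slice); physical voxel
spacing is never guessed: it must come from a JSON sidecar written next to
the TIFF, from embedded ImageJ-style metadata, or from an explicit override —
otherwise :class:`SpacingError` is raised.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .errors import SpacingError
from .grid import SegmentationMask, Spacing, VoxelGrid
from .phantom import PhantomTruth


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(grid: VoxelGrid | SegmentationMask, path: str | Path) -> Path:
    """Write a grid as multi-page TIFF plus a JSON sidecar with its geometry."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = grid.values
    if values.dtype == bool:
        data = values.astype(np.uint8) * 255
    else:
        data = values.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "spacing_um": list(grid.spacing),
        "time_hpf": grid.time,
        "channel": grid.channel,
        "binary": bool(values.dtype == bool),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _spacing_from_metadata(tif: tifffile.TiffFile) -> Optional[Spacing]:
    """Best-effort (sx, sy, sz) from ImageJ-style TIFF metadata, µm."""
    meta = tif.imagej_metadata or {}
    sz = meta.get("spacing")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if sz is None or xres is None or yres is None:
        return None
    def _per_px(tag) -> float:
        num, den = tag.value
        return den / num if num else 0.0
    sx, sy = _per_px(xres), _per_px(yres)
    if sx <= 0 or sy <= 0 or sz <= 0:
        return None
    return (float(sx), float(sy), float(sz))


def read_stack(
    path: str | Path,
    spacing: Optional[Spacing] = None,
    time: Optional[float] = None,
    channel: Optional[str] = None,
) -> VoxelGrid:
    """Load a multi-page TIFF as a :class:`VoxelGrid`.

    Spacing resolution order: explicit ``spacing`` override, JSON sidecar,
    embedded ImageJ metadata. 8- and 16-bit integer data load into floats
    without clipping. A missing file raises ``FileNotFoundError``; missing
    spacing raises :class:`SpacingError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    values = None
    meta_spacing = None
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        meta_spacing = _spacing_from_metadata(tif)
    if values.ndim == 2:
        values = values[None, ...]
    values = values.astype(np.float64)

    sidecar = _sidecar_path(path)
    side = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    resolved = spacing or (tuple(side["spacing_um"]) if "spacing_um" in side else None) or meta_spacing
    if resolved is None:
        raise SpacingError(
            f"{path}: no voxel spacing in sidecar or metadata and no override given; "
            "refusing to assume isotropy"
        )
    return VoxelGrid(
        values,
        tuple(float(s) for s in resolved),  # type: ignore[arg-type]
        time=time if time is not None else side.get("time_hpf"),
        channel=channel if channel is not None else side.get("channel"),
    )


def read_mask(path: str | Path, spacing: Optional[Spacing] = None) -> SegmentationMask:
    """Load a TIFF as a binary mask (foreground = any value above zero)."""
    grid = read_stack(path, spacing=spacing)
    return SegmentationMask(grid.values > 0, grid.spacing, time=grid.time, channel=grid.channel)


def write_truth(truth: PhantomTruth, path: str | Path) -> Path:
    """Serialize a :class:`PhantomTruth` (arrays as lists; masks omitted) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {}
    for f in dataclasses.fields(truth):
        if f.name in ("masks", "eye_masks"):
            continue
        val = getattr(truth, f.name)
        payload[f.name] = val.tolist() if isinstance(val, np.ndarray) else val
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth(path: str | Path) -> PhantomTruth:
    payload = json.loads(Path(path).read_text())
    kwargs = {
        k: (np.asarray(v) if isinstance(v, list) else v)
        for k, v in payload.items()
        if v is not None
    }
    kwargs.setdefault("times", np.asarray([]))
    return PhantomTruth(**kwargs)
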