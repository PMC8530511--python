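"""Growth kinetics: linear volume-vs-time slopes, fold-changes, slope ratios.

Tissue growth over the optic-vesicle folding window is well described by
plain linear trends in distinct time windows (e.g. a slow RPE volume drift
versus a ~25× faster whole-eye expansion), so ordinary least squares on the
frames inside a closed time window is the entire model — no robust or
weighted variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class GrowthFit:
    """OLS line fitted to volume (µm³) vs time (hpf) inside a window."""

    window: tuple[float, float]  # (t_start, t_end), hpf, closed interval
    slope: float  # µm³/hr
    intercept: float  # µm³ at t = 0
    r_squared: float
    n_frames: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def fit_growth_slope(
    times: Sequence[float],
    volumes: Sequence[float],
    window: tuple[float, float] | None = None,
) -> GrowthFit:
    """OLS slope of volume vs time over the frames inside a closed window.

    Frames exactly at a window boundary belong to the window. With
    ``window=None`` all frames are used.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and volumes must be 1D sequences of equal length")
    if window is None:
        window = (float(t.min()), float(t.max())) if t.size else (0.0, 0.0)
    t_start, t_end = float(window[0]), float(window[1])
    if not t_start < t_end:
        raise ValueError(f"window must satisfy t_start < t_end, got {window}")
    sel = (t >= t_start) & (t <= t_end)
    if int(sel.sum()) < 2:
        raise ValueError(f"need at least 2 frames inside window {window}, got {int(sel.sum())}")
    ts, vs = t[sel], v[sel]
    if np.ptp(ts) == 0:
        raise ValueError("frames inside the window share a single time point")
    res = stats.linregress(ts, vs)
    return GrowthFit(
        window=(t_start, t_end),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_frames=int(sel.sum()),
    )


def fold_change(series: Sequence[float]) -> float:
    """Last value over first value of a metric series."""
    s = np.asarray(series, dtype=float)
    if s.size < 1:
        raise ValueError("empty series")
    if s[0] == 0:
        raise ZeroDivisionError("fold change undefined: first value is zero")
    return float(s[-1] / s[0])


def slope_ratio(fit_a: GrowthFit | float, fit_b: GrowthFit | float) -> float:
    """Ratio of two growth slopes (how much faster a grows than b)."""
    a = fit_a.slope if isinstance(fit_a, GrowthFit) else float(fit_a)
    b = fit_b.slope if isinstance(fit_b, GrowthFit) else float(fit_b)
    if b == 0:
        raise ZeroDivisionError("slope ratio undefined: denominator slope is zero")
    return a / b
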