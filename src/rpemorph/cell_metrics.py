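"""Cell- and eye-shape measurements on coordinate lists.

Interactive drawing tools are replaced by plain coordinate inputs: an apical
cell outline is an ordered planar polygon, an apico-basal (A-B) length a pair
of points, and the invagination angle a vertex with two edge points (the
vertex sits at the centre of the basal surface of the neural retina, the edge
vectors reach the cup rim; smaller angles mean deeper folding). Experimental
eyes are normalized to the contralateral untreated eye to absorb
developmental asynchrony — values above 1 mean less flattening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import GeometryError


@dataclass
class CellOutline:
    """Ordered planar vertex list (µm) of one cell's apical contour."""

    vertices: np.ndarray  # (n, 2)
    plane_id: Optional[str] = None
    cell_class: Optional[Literal["progenitor", "NR", "RPE"]] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or self.vertices.shape[0] < 3:
            raise GeometryError("an outline needs at least 3 planar (x, y) vertices")


@dataclass
class AngleMeasurement:
    """Vertex and two edge points, in-plane (µm), for the invagination angle."""

    vertex: tuple[float, float]
    edge_a: tuple[float, float]
    edge_b: tuple[float, float]
    z_plane: Optional[str] = None


@dataclass
class ABLength:
    """Basal-to-apical line of one cell."""

    basal: tuple[float, float]
    apical: tuple[float, float]
    eye_id: Optional[str] = None
    treatment: Optional[str] = None


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _segments_properly_intersect(p: np.ndarray, q: np.ndarray, r: np.ndarray, s: np.ndarray) -> bool:
    """True when segments pq and rs cross at an interior point."""
    d1 = _cross2(q - p, r - p)
    d2 = _cross2(q - p, s - p)
    d3 = _cross2(s - r, p - r)
    d4 = _cross2(s - r, q - r)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def polygon_area(outline: CellOutline | Sequence[Sequence[float]]) -> float:
    """Shoelace area of a simple polygon, orientation-independent, in µm².

    Self-intersecting outlines raise :class:`GeometryError` (checked by
    pairwise proper-intersection of non-adjacent edges; fine for the small
    hand-traced contours this is meant for).
    """
    if not isinstance(outline, CellOutline):
        outline = CellOutline(np.asarray(outline, dtype=float))
    v = outline.vertices
    n = v.shape[0]
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_properly_intersect(*edges[i], *edges[j]):
                raise GeometryError("self-intersecting outline is not a simple polygon")
    x, y = v[:, 0], v[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    return float(abs(area2) / 2.0)


def ab_length(measure: ABLength | tuple[Sequence[float], Sequence[float]]) -> float:
    """Euclidean basal-to-apical distance in µm."""
    if isinstance(measure, ABLength):
        basal, apical = measure.basal, measure.apical
    else:
        basal, apical = measure
    b = np.asarray(basal, dtype=float)
    a = np.asarray(apical, dtype=float)
    d = float(np.linalg.norm(a - b))
    if d == 0:
        raise GeometryError("basal and apical points coincide; length undefined")
    return d


def normalize_to_contralateral(experimental: float, control: float) -> float:
    """Experimental / contralateral-control ratio (dimensionless).

    Values above 1 indicate less flattening (longer cells, wider angles) in
    the experimental eye than in its untreated contralateral control.
    """
    if control <= 0:
        raise ZeroDivisionError(f"control value must be positive, got {control}")
    return experimental / control


def invagination_angle(m: AngleMeasurement) -> float:
    """Interior angle at the vertex between the two vertex-to-edge vectors, degrees."""
    vtx = np.asarray(m.vertex, dtype=float)
    a = np.asarray(m.edge_a, dtype=float) - vtx
    b = np.asarray(m.edge_b, dtype=float) - vtx
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise GeometryError("edge point coincides with the vertex; angle undefined")
    cosang = float(np.dot(a, b) / (na * nb))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
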