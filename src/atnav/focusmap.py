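"""Focus surface from scattered user anchors.

During acquisition the optical microscope needs a focus value z at every
stage position. Users drop a handful of focus anchors per ribbon; inside
their convex hull the surface is interpolated with Sibson's natural-neighbor
method (exact at anchors, linear precision, C1 away from them), outside it
the nearest anchor's z is used and the query flagged as extrapolated.

Sibson coordinates are computed from first principles: the query point is
inserted into the anchors' Voronoi diagram and each weight is the area its
new cell steals from an existing cell, normalized. Cells are made finite by
distant ghost sites; for queries inside the convex hull the stolen areas are
unaffected by the ghosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi
from shapely.geometry import Polygon

__all__ = ["FocusMap", "FocusResult", "interpolate_focus"]


@dataclass(frozen=True)
class FocusResult:
    z: float
    extrapolated: bool


class FocusMap:
    """Scattered (x, y, z) focus anchors in stage micrometres."""

    def __init__(self, anchors):
        a = np.atleast_2d(np.asarray(anchors, dtype=float))
        if a.size == 0 or a.shape[1] != 3:
            raise ValueError("anchors must be an (n, 3) array of (x, y, z)")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite anchor")
        # reject duplicate planar positions (ambiguous z)
        xy = a[:, :2]
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                if np.allclose(xy[i], xy[j], atol=1e-9):
                    raise ValueError(f"anchors {i} and {j} share a position")
        self.anchors = a

    def add(self, x: float, y: float, z: float) -> "FocusMap":
        return FocusMap(np.vstack([self.anchors, [x, y, z]]))

    def __len__(self) -> int:
        return len(self.anchors)

    # -- interpolation ------------------------------------------------------

    def _degenerate(self) -> bool:
        """Fewer than 3 anchors, or all (nearly) collinear."""
        if len(self.anchors) < 3:
            return True
        xy = self.anchors[:, :2]
        d = xy - xy.mean(axis=0)
        # smallest singular value ~ 0 => collinear
        s = np.linalg.svd(d, compute_uv=False)
        return s[-1] < 1e-9 * max(s[0], 1.0)

    def _nearest(self, x: float, y: float) -> float:
        d = np.hypot(self.anchors[:, 0] - x, self.anchors[:, 1] - y)
        return float(self.anchors[int(np.argmin(d)), 2])

    def __call__(self, x: float, y: float) -> FocusResult:
        return interpolate_focus(self, x, y)


def _ghosted_voronoi(xy: np.ndarray) -> Tuple[Voronoi, int]:
    """Voronoi diagram of the sites plus 4 distant ghost sites, which bounds
    every real cell near the data."""
    span = float(np.ptp(xy, axis=0).max()) or 1.0
    cx, cy = xy.mean(axis=0)
    r = 1e4 * span
    ghosts = np.array([[cx - r, cy], [cx + r, cy], [cx, cy - r], [cx, cy + r]])
    return Voronoi(np.vstack([xy, ghosts])), len(xy)


def _cell_polygons(vor: Voronoi, n_real: int) -> List[Polygon]:
    polys = []
    for i in range(n_real):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            polys.append(None)
            continue
        polys.append(Polygon(vor.vertices[region]))
    return polys


def _sibson_weights(xy: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Weights of each anchor for query q strictly inside the convex hull."""
    n = len(xy)
    base_vor, _ = _ghosted_voronoi(xy)
    base_cells = _cell_polygons(base_vor, n)
    aug_vor, _ = _ghosted_voronoi(np.vstack([xy, q]))
    # the inserted point is the last real site of the augmented diagram
    region = aug_vor.regions[aug_vor.point_region[n + 0]]
    # note: augmented diagram sites order = [xy..., q, ghosts]; point n is q
    if -1 in region or len(region) < 3:
        raise QhullError("query cell unbounded")
    qcell = Polygon(aug_vor.vertices[region])
    w = np.zeros(n)
    for i, cell in enumerate(base_cells):
        if cell is None:
            continue
        inter = qcell.intersection(cell)
        if not inter.is_empty:
            w[i] = inter.area
    total = w.sum()
    if total <= 0:
        raise QhullError("degenerate Sibson cell")
    return w / total


def interpolate_focus(fmap: FocusMap, x: float, y: float) -> FocusResult:
    """Focus z at stage position (x, y).

    Sibson natural-neighbor interpolation inside the anchors' convex hull
    (exact at anchors, linear precision); nearest-anchor fallback outside the
    hull or whenever fewer than three non-collinear anchors exist, flagged
    as extrapolated.
    """
    a = fmap.anchors
    # exact at anchors regardless of configuration
    d = np.hypot(a[:, 0] - x, a[:, 1] - y)
    hit = int(np.argmin(d))
    span = max(float(np.ptp(a[:, :2])), 1.0)
    if d[hit] < 1e-9 * span:
        return FocusResult(float(a[hit, 2]), extrapolated=False)

    if fmap._degenerate():
        return FocusResult(fmap._nearest(x, y), extrapolated=True)

    xy = a[:, :2]
    try:
        tri = Delaunay(xy)
    except QhullError:
        return FocusResult(fmap._nearest(x, y), extrapolated=True)
    if tri.find_simplex(np.array([x, y])) < 0:
        return FocusResult(fmap._nearest(x, y), extrapolated=True)
    try:
        w = _sibson_weights(xy, np.array([x, y]))
    except QhullError:
        return FocusResult(fmap._nearest(x, y), extrapolated=True)
    return FocusResult(float(w @ a[:, 2]), extrapolated=False)
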