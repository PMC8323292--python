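"""Overview-image construction and the section-boundary preprocessing pipeline.

The overview mosaic anchors the absolute coordinate frame of the whole run:
tile offsets are estimated pairwise by phase correlation on the nominal
overlap strips, reconciled by a global least-squares solve over the grid
graph, and blended with a linear feather. Preprocessing then turns the
brightfield overview into a non-negative edge-response map — contrast
normalization, Gaussian blur, Laplacian, threshold, size filter,
morphological smoothing — on which section boundaries are ridges of maxima
for the active-contour fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import tifffile
from scipy import ndimage
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import lsqr
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing as _closing, opening as _opening, disk
from skimage.registration import phase_cross_correlation

__all__ = [
    "OverviewImage",
    "TileGrid",
    "EdgeMap",
    "EmptyForegroundError",
    "grid_stitch",
    "preprocess_overview",
]


@dataclass
class OverviewImage:
    """Stitched grayscale overview; ``pixel_size`` in μm/px."""

    pixels: np.ndarray
    pixel_size: float
    bit_depth: int = 8

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 64:
            raise ValueError("overview must be a 2D image of at least 64x64")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def pixels_per_um(self) -> float:
        return 1.0 / self.pixel_size

    def save(self, path: str) -> None:
        res = 1.0 / (self.pixel_size * 1e-4)  # px per cm
        tifffile.imwrite(path, self.pixels, resolution=(res, res),
                         resolutionunit="CENTIMETER")

    @classmethod
    def load(cls, path: str, pixel_size: Optional[float] = None) -> "OverviewImage":
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            arr = page.asarray()
            if pixel_size is None:
                try:
                    xres = page.tags["XResolution"].value
                    unit = page.tags["ResolutionUnit"].value
                    per_cm = xres[0] / xres[1]
                    if int(unit) == 2:  # inch
                        per_cm = per_cm / 2.54
                    pixel_size = 1e4 / per_cm
                except (KeyError, ZeroDivisionError):
                    raise ValueError("TIFF carries no resolution tag; pass pixel_size")
        depth = 16 if arr.dtype.itemsize > 1 else 8
        return cls(pixels=arr, pixel_size=float(pixel_size), bit_depth=depth)


@dataclass
class TileGrid:
    """Row-major overlapping tile set with a nominal overlap fraction."""

    tiles: List[np.ndarray]
    rows: int
    cols: int
    nominal_overlap: float

    def __post_init__(self):
        if self.rows * self.cols != len(self.tiles):
            raise ValueError("rows*cols != number of tiles")
        if not 0 < self.nominal_overlap < 0.5:
            raise ValueError("nominal_overlap must be in (0, 0.5)")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) != 1:
            raise ValueError("all tiles must share one shape")

    @property
    def tile_shape(self) -> Tuple[int, int]:
        return self.tiles[0].shape


@dataclass
class EdgeMap:
    """Non-negative edge response registered to its source overview, with the
    stage list and parameters that produced it (for provenance)."""

    response: np.ndarray
    pixel_size: float
    stages: List[dict] = field(default_factory=list)

    def save(self, path: str) -> None:
        tifffile.imwrite(path, self.response.astype(np.float32))


class EmptyForegroundError(RuntimeError):
    """A preprocessing stage removed all foreground; names the stage."""

    def __init__(self, stage: str):
        super().__init__(f"empty foreground after stage {stage!r}")
        self.stage = stage


# ---------------------------------------------------------------------------
# grid stitching
# ---------------------------------------------------------------------------

def _overlap_ncc(a: np.ndarray, b: np.ndarray, dy: int, dx: int) -> float:
    """Normalized cross-correlation of the region where tile b (origin at
    a's origin + (dy, dx)) overlaps tile a; -2 if the overlap is too small."""
    ya, yb = max(0, dy), max(0, -dy)
    xa, xb = max(0, dx), max(0, -dx)
    h = min(a.shape[0] - ya, b.shape[0] - yb)
    w = min(a.shape[1] - xa, b.shape[1] - xb)
    if h < 12 or w < 12:
        return -2.0
    pa = a[ya:ya + h, xa:xa + w]
    pb = b[yb:yb + h, xb:xb + w]
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    denom = np.sqrt((pa * pa).sum() * (pb * pb).sum())
    if denom < 1e-9:
        return -2.0
    return float((pa * pb).sum() / denom)


def _pair_offset(a: np.ndarray, b: np.ndarray, axis: int, overlap_px: int,
                 search_px: int = 8):
    """Offset of tile b's origin relative to a's for a horizontal (axis=1) or
    vertical (axis=0) neighbour pair. Returns (dy, dx, ok).

    A phase-correlation estimate on the nominal overlap strips seeds a local
    normalized-cross-correlation search around the nominal offset; the NCC
    verification is what disambiguates straight section boundaries, whose
    translation symmetry can make the raw phase peak sit on a ridge.
    """
    a = a.astype(float)
    b = b.astype(float)
    if axis == 1:
        sa, sb = a[:, -overlap_px:], b[:, :overlap_px]
        nominal = np.array([0.0, a.shape[1] - overlap_px])
    else:
        sa, sb = a[-overlap_px:, :], b[:overlap_px, :]
        nominal = np.array([a.shape[0] - overlap_px, 0.0])
    if sa.std() < 1e-3 or sb.std() < 1e-3:
        return nominal[0], nominal[1], False

    cands = {(0, 0)}
    shift, _, _ = phase_cross_correlation(sa, sb, upsample_factor=1,
                                          normalization="phase")
    if np.all(np.abs(shift) <= overlap_px / 2):
        cands.add((int(round(shift[0])), int(round(shift[1]))))
    for r in range(-search_px, search_px + 1):
        for c in range(-search_px, search_px + 1):
            cands.add((r, c))

    ny, nx = int(round(nominal[0])), int(round(nominal[1]))
    scored = {}
    for (r, c) in cands:
        scored[(r, c)] = _overlap_ncc(a, b, ny + r, nx + c)
    best = max(scored, key=scored.get)
    best_ncc = scored[best]
    if best_ncc < 0.5:
        return nominal[0], nominal[1], False

    # quadratic sub-pixel refinement on the NCC surface
    def refine(axis_idx):
        lo = tuple(np.add(best, (-1, 0) if axis_idx == 0 else (0, -1)))
        hi = tuple(np.add(best, (1, 0) if axis_idx == 0 else (0, 1)))
        m = scored.get(lo, _overlap_ncc(a, b, ny + lo[0], nx + lo[1]))
        p = scored.get(hi, _overlap_ncc(a, b, ny + hi[0], nx + hi[1]))
        c0 = best_ncc
        denom = m - 2 * c0 + p
        if denom >= 0 or m < -1 or p < -1:
            return 0.0
        return float(np.clip(0.5 * (m - p) / denom, -0.5, 0.5))

    dy = nominal[0] + best[0] + refine(0)
    dx = nominal[1] + best[1] + refine(1)
    return float(dy), float(dx), True


def grid_stitch(grid: TileGrid, return_offsets: bool = False):
    """Assemble a mosaic from an overlapping tile grid.

    Pairwise offsets between 4-neighbours come from phase correlation; global
    tile positions are the least-squares solution of the offset graph
    anchored at tile (0,0); overlaps are feather-blended. Featureless
    overlaps fall back to the nominal grid offset with a warning.
    """
    R, C = grid.rows, grid.cols
    th, tw = grid.tile_shape
    if R * C == 1:
        img = grid.tiles[0]
        out = OverviewImage(pixels=img.copy(), pixel_size=1.0,
                            bit_depth=16 if img.dtype.itemsize > 1 else 8)
        return (out, np.zeros((1, 2))) if return_offsets else out
    ov_y = max(8, int(round(th * grid.nominal_overlap)))
    ov_x = max(8, int(round(tw * grid.nominal_overlap)))

    edges = []  # (i, j, dy, dx, weight)
    n_fallback = 0
    for r in range(R):
        for c in range(C):
            i = r * C + c
            if c + 1 < C:
                dy, dx, ok = _pair_offset(grid.tiles[i], grid.tiles[i + 1], 1, ov_x)
                edges.append((i, i + 1, dy, dx, 1.0 if ok else 0.05))
                n_fallback += not ok
            if r + 1 < R:
                dy, dx, ok = _pair_offset(grid.tiles[i], grid.tiles[i + C], 0, ov_y)
                edges.append((i, i + C, dy, dx, 1.0 if ok else 0.05))
                n_fallback += not ok
    if n_fallback:
        warnings.warn(f"{n_fallback} featureless overlap(s); nominal offsets used")

    # weighted least squares: positions p_j - p_i = measured offset, p_0 = 0;
    # nominal-fallback constraints get low weight so they only pin tiles the
    # measured graph leaves free
    n = R * C
    A = lil_matrix((len(edges) + 1, n))
    by = np.zeros(len(edges) + 1)
    bx = np.zeros(len(edges) + 1)
    for k, (i, j, dy, dx, w) in enumerate(edges):
        A[k, i], A[k, j] = -w, w
        by[k], bx[k] = w * dy, w * dx
    A[len(edges), 0] = 1.0  # anchor
    A = A.tocsr()
    py = lsqr(A, by)[0]
    px = lsqr(A, bx)[0]
    py -= py.min()
    px -= px.min()
    offsets = np.column_stack([py, px])

    H = int(np.ceil(py.max())) + th
    W = int(np.ceil(px.max())) + tw
    acc = np.zeros((H, W))
    wgt = np.zeros((H, W))
    # linear feather: weight falls to zero at tile borders
    fy = np.minimum(np.arange(th) + 1, np.arange(th)[::-1] + 1).astype(float)
    fx = np.minimum(np.arange(tw) + 1, np.arange(tw)[::-1] + 1).astype(float)
    feather = np.minimum.outer(fy / fy.max(), fx / fx.max())
    for i, tile in enumerate(grid.tiles):
        oy, ox = int(round(py[i])), int(round(px[i]))
        acc[oy:oy + th, ox:ox + tw] += tile.astype(float) * feather
        wgt[oy:oy + th, ox:ox + tw] += feather
    mosaic = acc / np.maximum(wgt, 1e-12)
    dtype = grid.tiles[0].dtype
    maxval = 65535 if dtype.itemsize > 1 else 255
    mosaic = np.clip(np.round(mosaic), 0, maxval).astype(dtype)
    out = OverviewImage(pixels=mosaic, pixel_size=1.0,
                        bit_depth=16 if dtype.itemsize > 1 else 8)
    return (out, offsets) if return_offsets else out


# ---------------------------------------------------------------------------
# preprocessing pipeline
# ---------------------------------------------------------------------------

_DEFAULT_STAGES = ("normalize", "blur", "laplacian", "threshold", "size_filter", "smooth")


def preprocess_overview(
    img: OverviewImage,
    stretch_percentiles: Tuple[float, float] = (0.5, 99.5),
    sigma_blur_px: float = 2.0,
    min_area_px: int = 100,
    edge_soft_px: float = 3.0,
    stages: Tuple[str, ...] = _DEFAULT_STAGES,
) -> EdgeMap:
    """Turn the brightfield overview into an edge-response map in [0, 1].

    Ordered, individually switchable stages: (1) percentile contrast stretch,
    (2) Gaussian blur, (3) Laplacian magnitude, (4) Otsu threshold to a
    boundary mask, (5) connected-component size filter, (6) morphological
    closing/opening. The response is the Laplacian magnitude under the
    cleaned mask (so stronger boundaries score higher than faint clutter
    such as glue edges), softened by a small Gaussian so the active contour
    sees a smooth basin around each ridge. Section boundaries are maxima of
    the result; the map is invariant to affine intensity changes of the
    input through stage (1).
    """
    unknown = set(stages) - set(_DEFAULT_STAGES)
    if unknown:
        raise ValueError(f"unknown preprocessing stage(s): {sorted(unknown)}")
    x = img.pixels.astype(np.float64)
    meta: List[dict] = []
    lap_mag = None

    if "normalize" in stages:
        lo, hi = np.percentile(x, stretch_percentiles)
        if hi <= lo:
            hi = lo + 1.0
        x = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        meta.append({"stage": "normalize", "percentiles": list(stretch_percentiles)})
    if "blur" in stages:
        x = ndimage.gaussian_filter(x, sigma_blur_px)
        meta.append({"stage": "blur", "sigma_px": sigma_blur_px})
    if "laplacian" in stages:
        x = np.abs(ndimage.laplace(x))
        lap_mag = x
        meta.append({"stage": "laplacian"})

    if "threshold" in stages:
        if x.max() <= 0:
            mask = np.zeros(x.shape, bool)
        else:
            mask = x > threshold_otsu(x)
        if not mask.any():
            raise EmptyForegroundError("threshold")
        meta.append({"stage": "threshold", "method": "otsu"})
    else:
        mask = x > 0

    if "size_filter" in stages:
        lab, nlab = label(mask, return_num=True, connectivity=2)
        if nlab:
            sizes = np.bincount(lab.ravel())
            keep = sizes >= min_area_px
            keep[0] = False
            mask = keep[lab]
        if "threshold" in stages and not mask.any():
            raise EmptyForegroundError("size_filter")
        meta.append({"stage": "size_filter", "min_area_px": min_area_px})
    if "smooth" in stages:
        se = disk(2)
        mask = _opening(_closing(mask, se), se)
        if "threshold" in stages and not mask.any():
            raise EmptyForegroundError("smooth")
        meta.append({"stage": "smooth", "selem": "disk(2)"})

    response = mask.astype(np.float64)
    if lap_mag is not None:
        response = response * lap_mag
    if edge_soft_px > 0:
        response = ndimage.gaussian_filter(response, edge_soft_px)
        meta.append({"stage": "soften", "sigma_px": edge_soft_px})
    m = response.max()
    if m > 0:
        response = response / m
    return EdgeMap(response=response, pixel_size=img.pixel_size, stages=meta)
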