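"""Synthetic array-tomography scenes and a simulated microscope.

The generator emulates the physical sample the navigation workflow was built
for: ribbons of trapezoidal ~150 nm resin sections deposited in cutting order
on an ITO coverslip, imaged in transmitted light. Section shape drifts
gradually along a ribbon (block trimming, compression), glue strips darken the
leading/trailing edges, and each tracked ROI corresponds to a persistent dark
intracellular structure (a stand-in for a Golgi impregnation deposit) whose
centroid drifts slowly from section to section. The ground-truth geometry —
section polygons, ROI trajectories, focus surface — is exported so every
detection and navigation operation can be scored without reading scene
internals.

All scene geometry lives in stage micrometres with the origin at the top-left
of the overview raster, x right, y down. Rendering at P pixels/μm places the
stage point (x, y) at pixel column x·P, row y·P.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import FOV_PX, MAG_PIXELS_PER_UM
from .geometry import NaturalPoint, Point2D, SectionQuad, forward_map

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "LayoutError",
    "generate_scene",
    "render_overview",
    "render_tiles",
    "render_region",
    "degrade_image",
    "SimulatedMicroscope",
]

COVERSLIP_UM = 22_000.0  # 22 x 22 mm ITO coverslip

# rendering gray levels (8-bit brightfield-like)
_BG = 228.0
_INTERIOR = 175.0
_GLUE = 132.0
_BOUNDARY = 55.0
_STRUCTURE = 35.0


class LayoutError(ValueError):
    """Requested scene geometry is infeasible (overlapping sections, raster
    too large, or exceeding the coverslip)."""


@dataclass
class SceneParams:
    """Generator knobs; defaults reproduce the proof-of-concept layout of
    6 ribbons totalling 126 sections (15-27 per ribbon).

    Units are micrometres unless stated. ``shrink_per_section`` is the
    fractional linear shrink per cut; ``shear_per_section`` tilts the
    trailing edge; ``curvature_deg_per_section`` bends the ribbon axis;
    ``ribbon_rotation_deg`` is the max |rotation| of a whole ribbon
    (supported up to 45).
    """

    n_ribbons: int = 6
    total_sections: int = 126
    sections_per_ribbon: Optional[Tuple[int, ...]] = None  # overrides total
    section_width_um: float = 110.0
    section_height_um: float = 70.0
    trapezoid_taper: float = 0.12  # trailing edge narrower by this fraction
    section_gap_um: float = 6.0
    glue_strip_um: float = 4.0
    ribbon_spacing_um: float = 185.0
    margin_um: float = 45.0
    shrink_per_section: float = 0.002
    shear_per_section: float = 0.001
    curvature_deg_per_section: float = 0.0
    ribbon_rotation_deg: float = 1.0
    corner_jitter_um: float = 0.8
    n_rois: int = 1
    roi_drift_um_per_section: float = 0.4
    roi_structure_radius_um: float = 4.0
    # focus surface z(x,y) = z0 + gx*x + gy*y + amp*sin(x/L)*cos(y/L)
    focus_z0_um: float = 50.0
    focus_tilt: Tuple[float, float] = (0.003, 0.002)
    focus_ripple_um: float = 1.0
    focus_length_um: float = 900.0

    def __post_init__(self):
        if self.n_ribbons < 1:
            raise LayoutError("need at least one ribbon")
        if not (0 <= self.trapezoid_taper < 0.9):
            raise LayoutError("trapezoid_taper out of range")
        if abs(self.ribbon_rotation_deg) > 45:
            raise LayoutError("ribbon rotation supported up to 45 degrees")


@dataclass
class RoiTruth:
    """Ground truth for one tracked structure: its home ribbon, its natural
    address, the dark-lobe geometry (local μm offsets/radii), and the stage
    trajectory (one point per section of its ribbon)."""

    ribbon: int
    natural: Tuple[float, float]
    lobes: List[Tuple[float, float, float]]  # (dx, dy, radius) μm
    trajectory_um: np.ndarray  # (n_sections, 2)


@dataclass
class SyntheticScene:
    """Fully deterministic ground-truth scene: (params, seed) fixes every
    polygon, trajectory and texture sample."""

    params: SceneParams
    seed: int
    ribbons_um: List[List[np.ndarray]]  # per ribbon: list of (4,2) corner arrays
    rois: List[RoiTruth]
    _tex_cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- ground-truth accessors ---------------------------------------------

    @property
    def n_sections(self) -> int:
        return sum(len(r) for r in self.ribbons_um)

    def section_quad(self, ribbon: int, section: int) -> SectionQuad:
        return SectionQuad(self.ribbons_um[ribbon][section].copy())

    def quads_px(self, ribbon: int, pixels_per_um: float) -> List[np.ndarray]:
        return [c * pixels_per_um for c in self.ribbons_um[ribbon]]

    def all_quads_px(self, pixels_per_um: float) -> List[List[np.ndarray]]:
        return [self.quads_px(r, pixels_per_um) for r in range(len(self.ribbons_um))]

    def focus_z(self, x_um, y_um):
        p = self.params
        return (
            p.focus_z0_um
            + p.focus_tilt[0] * np.asarray(x_um)
            + p.focus_tilt[1] * np.asarray(y_um)
            + p.focus_ripple_um
            * np.sin(np.asarray(x_um) / p.focus_length_um)
            * np.cos(np.asarray(y_um) / p.focus_length_um)
        )

    def bounds_um(self) -> Tuple[float, float]:
        """(width, height) of the scene raster in μm including margins."""
        all_c = np.concatenate([c for r in self.ribbons_um for c in r])
        return (
            float(all_c[:, 0].max() + self.params.margin_um),
            float(all_c[:, 1].max() + self.params.margin_um),
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str) -> None:
        d = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.params).items()},
            "seed": self.seed,
            "ribbons_um": [[c.tolist() for c in r] for r in self.ribbons_um],
            "rois": [
                {
                    "ribbon": r.ribbon,
                    "natural": list(r.natural),
                    "lobes": [list(l) for l in r.lobes],
                    "trajectory_um": r.trajectory_um.tolist(),
                }
                for r in self.rois
            ],
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticScene":
        with open(path) as fh:
            d = json.load(fh)
        p = d["params"]
        for k in ("sections_per_ribbon", "focus_tilt"):
            if p.get(k) is not None:
                p[k] = tuple(p[k])
        return cls(
            params=SceneParams(**p),
            seed=d["seed"],
            ribbons_um=[[np.array(c, float) for c in r] for r in d["ribbons_um"]],
            rois=[
                RoiTruth(
                    ribbon=r["ribbon"],
                    natural=tuple(r["natural"]),
                    lobes=[tuple(l) for l in r["lobes"]],
                    trajectory_um=np.array(r["trajectory_um"], float),
                )
                for r in d["rois"]
            ],
        )


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _section_counts(params: SceneParams, rng: np.random.Generator) -> List[int]:
    if params.sections_per_ribbon is not None:
        counts = list(params.sections_per_ribbon)
        if len(counts) != params.n_ribbons:
            raise LayoutError("sections_per_ribbon length != n_ribbons")
        return counts
    lo, hi = 15, 27
    n, total = params.n_ribbons, params.total_sections
    if not (n * lo <= total <= n * hi):
        # fall back to an even split when the 15-27 band cannot hold the total
        base = total // n
        counts = [base] * n
        for i in range(total - base * n):
            counts[i] += 1
        return counts
    counts = list(rng.integers(lo, hi + 1, size=n))
    while sum(counts) != total:
        i = int(rng.integers(n))
        if sum(counts) < total and counts[i] < hi:
            counts[i] += 1
        elif sum(counts) > total and counts[i] > lo:
            counts[i] -= 1
    return counts


def _local_trapezoid(p: SceneParams, s: int) -> np.ndarray:
    """Corner offsets (μm) of section s of a ribbon around its centre, before
    ribbon rotation: leading (top) edge full width, trailing edge tapered,
    linear shrink and shear accumulating along the ribbon."""
    scale = (1.0 - p.shrink_per_section) ** s
    w_top = p.section_width_um * scale
    w_bot = p.section_width_um * (1.0 - p.trapezoid_taper) * scale
    h = p.section_height_um * scale
    shear = p.shear_per_section * s * h
    return np.array(
        [
            [-w_top / 2, -h / 2],
            [w_top / 2, -h / 2],
            [w_bot / 2 + shear, h / 2],
            [-w_bot / 2 + shear, h / 2],
        ]
    )


def _rot(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def generate_scene(params: SceneParams = None, seed: int = 0) -> SyntheticScene:
    """Build a ground-truth scene; deterministic for (params, seed)."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    counts = _section_counts(params, rng)

    ribbons: List[List[np.ndarray]] = []
    for r, count in enumerate(counts):
        theta0 = float(rng.uniform(-params.ribbon_rotation_deg, params.ribbon_rotation_deg))
        x0 = params.margin_um + params.section_width_um / 2 + r * params.ribbon_spacing_um
        y0 = params.margin_um + params.section_height_um / 2
        pitch = params.section_height_um + params.section_gap_um
        pos = np.array([x0, y0], float)
        quads = []
        theta = theta0
        for s in range(count):
            jitter = rng.uniform(-params.corner_jitter_um, params.corner_jitter_um, (4, 2))
            local = _local_trapezoid(params, s) + jitter
            corners = pos + local @ _rot(theta).T
            quad = SectionQuad(corners)  # validates order/convexity
            quads.append(quad.corners)
            # advance along the (possibly curving) ribbon axis
            theta += params.curvature_deg_per_section
            step = _rot(theta) @ np.array([0.0, pitch])
            pos = pos + step
        ribbons.append(quads)

    _check_layout(ribbons, params)

    scene = SyntheticScene(params=params, seed=seed, ribbons_um=ribbons, rois=[])
    scene.rois.extend(_make_rois(scene, rng))
    return scene


def _check_layout(ribbons, params) -> None:
    from shapely.geometry import Polygon
    from shapely.strtree import STRtree

    polys = [Polygon(c) for r in ribbons for c in r]
    all_c = np.concatenate([c for r in ribbons for c in r])
    if all_c.min() < 0 or all_c.max() > COVERSLIP_UM:
        raise LayoutError("scene exceeds the 22 x 22 mm coverslip")
    tree = STRtree(polys)
    for i, p in enumerate(polys):
        for j in tree.query(p):
            j = int(j)
            if j != i and polys[j].intersection(p).area > 1e-9:
                raise LayoutError(f"sections {i} and {j} overlap; layout infeasible")


def _make_rois(scene: SyntheticScene, rng: np.random.Generator) -> List[RoiTruth]:
    p = scene.params
    rois = []
    for i in range(p.n_rois):
        ribbon = i % len(scene.ribbons_um)
        nat = NaturalPoint(*rng.uniform(-0.35, 0.35, 2))
        # persistent multi-lobed dark structure, fixed local shape
        n_lobes = int(rng.integers(3, 6))
        offs = rng.uniform(-p.roi_structure_radius_um, p.roi_structure_radius_um, (n_lobes, 2))
        rads = rng.uniform(0.35, 0.6, n_lobes) * p.roi_structure_radius_um
        # recentre so the area-weighted lobe centroid sits on the trajectory
        w = rads**2 / (rads**2).sum()
        offs = offs - w @ offs
        lobes = [(float(ox), float(oy), float(r_)) for (ox, oy), r_ in zip(offs, rads)]
        # trajectory: transfinite address + slow cumulative drift (zero at
        # the anchor section so the user's click is exact there)
        quads = scene.ribbons_um[ribbon]
        traj = np.zeros((len(quads), 2))
        drift = np.zeros(2)
        for s, corners in enumerate(quads):
            base = forward_map(SectionQuad(corners), nat).as_array()
            traj[s] = base + drift
            step = rng.uniform(-1, 1, 2)
            nrm = np.linalg.norm(step)
            if nrm > 0:
                step = step / nrm * rng.uniform(0, p.roi_drift_um_per_section)
            drift = drift + step
        rois.append(RoiTruth(ribbon=ribbon, natural=(nat.xi, nat.eta),
                             lobes=lobes, trajectory_um=traj))
    return rois


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_MAX_RASTER_PX = 120_000_000


def _lattice(scene: SyntheticScene, key: tuple, shape: tuple, spacing: float,
             smooth: float) -> np.ndarray:
    """Seeded smooth value lattice; cached so every render of the same scene
    samples the same texture."""
    cache_key = (key, shape, spacing)
    if cache_key not in scene._tex_cache:
        import zlib

        stable = [
            zlib.crc32(k.encode()) & 0x7FFFFFFF if isinstance(k, str) else int(k) & 0x7FFFFFFF
            for k in key
        ]
        rng = np.random.default_rng([scene.seed & 0x7FFFFFFF, *stable])
        lat = rng.standard_normal(shape)
        lat = ndimage.gaussian_filter(lat, smooth)
        sd = lat.std()
        if sd > 0:
            lat = lat / sd
        scene._tex_cache[cache_key] = lat
    return scene._tex_cache[cache_key]


def _ribbon_texture(scene: SyntheticScene, r: int, spacing: float = 2.0,
                    rho: float = 0.85) -> np.ndarray:
    """Per-ribbon stack of interior texture lattices, one per section,
    evolving as an AR(1) chain along the cutting order: consecutive 150 nm
    sections of real tissue are highly similar, so neighbouring sections
    must correlate for stack registration to have the signal it has on real
    data. Anchored at each section's bounding-box origin (texture follows
    the section)."""
    key = ("texchain", r, spacing)
    if key not in scene._tex_cache:
        quads = scene.ribbons_um[r]
        ext = np.max([c.max(axis=0) - c.min(axis=0) for c in quads], axis=0) + 20
        shape = (int(ext[1] / spacing) + 3, int(ext[0] / spacing) + 3)
        import zlib

        rng = np.random.default_rng(
            [scene.seed & 0x7FFFFFFF, zlib.crc32(b"texchain") & 0x7FFFFFFF, r]
        )
        chain = np.empty((len(quads),) + shape)
        cur = ndimage.gaussian_filter(rng.standard_normal(shape), 0.8)
        for s in range(len(quads)):
            if s > 0:
                innov = ndimage.gaussian_filter(rng.standard_normal(shape), 0.8)
                cur = rho * cur + np.sqrt(1 - rho**2) * innov
            sd = cur.std()
            chain[s] = cur / sd if sd > 0 else cur
        scene._tex_cache[key] = chain
    return scene._tex_cache[key]


def _sample_lattice(lat: np.ndarray, x_um, y_um, x0: float, y0: float,
                    spacing: float) -> np.ndarray:
    ci = (np.asarray(y_um) - y0) / spacing
    cj = (np.asarray(x_um) - x0) / spacing
    return ndimage.map_coordinates(lat, [ci, cj], order=1, mode="nearest")


def _seg_dist(px, py, a, b):
    """Vectorized point-to-segment distance."""
    ab = b - a
    denom = float(ab @ ab)
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / max(denom, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))


def render_region(
    scene: SyntheticScene,
    x0_um: float,
    y0_um: float,
    shape_px: Tuple[int, int],
    pixels_per_um: float,
    optics_blur_um: float = 0.2,
) -> np.ndarray:
    """Render a brightfield-like 8-bit view of the scene window whose top-left
    pixel samples stage position (x0_um, y0_um). One code path serves the
    overview, the tile grid and the simulated camera, so geometry is
    consistent across magnifications by construction."""
    h, w = shape_px
    if h * w > _MAX_RASTER_PX:
        raise LayoutError(f"raster {w}x{h} exceeds the size limit")
    p = scene.params
    img = np.full((h, w), _BG, dtype=np.float64)

    # coverslip-scale background mottle (8 μm lattice over the whole scene)
    bw, bh = scene.bounds_um()
    bg_spacing = 8.0
    bg_lat = _lattice(scene, ("bg",), (int(bh / bg_spacing) + 3, int(bw / bg_spacing) + 3),
                      bg_spacing, 1.0)
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    X = x0_um + jj / pixels_per_um
    Y = y0_um + ii / pixels_per_um
    img += 3.0 * _sample_lattice(bg_lat, X, Y, 0.0, 0.0, bg_spacing)

    win_x1, win_y1 = x0_um + w / pixels_per_um, y0_um + h / pixels_per_um
    boundary_half_um = 0.5
    glue = p.glue_strip_um

    for r, quads in enumerate(scene.ribbons_um):
        for s, corners in enumerate(quads):
            cx0, cy0 = corners.min(axis=0) - (glue + 3)
            cx1, cy1 = corners.max(axis=0) + (glue + 3)
            if cx1 < x0_um or cy1 < y0_um or cx0 > win_x1 or cy0 > win_y1:
                continue
            j0 = max(0, int((cx0 - x0_um) * pixels_per_um))
            j1 = min(w, int((cx1 - x0_um) * pixels_per_um) + 2)
            i0 = max(0, int((cy0 - y0_um) * pixels_per_um))
            i1 = min(h, int((cy1 - y0_um) * pixels_per_um) + 2)
            if j1 <= j0 or i1 <= i0:
                continue
            lx = X[i0:i1, j0:j1]
            ly = Y[i0:i1, j0:j1]
            sub = img[i0:i1, j0:j1]

            # glue strips outside the leading (0-1) and trailing (2-3) edges
            for (a_idx, b_idx) in ((0, 1), (2, 3)):
                a, b = corners[a_idx], corners[b_idx]
                d = _seg_dist(lx, ly, a, b)
                edge = b - a
                # outward normal: for edge 0-1 it is -axis, for 2-3 +axis
                nrm = np.array([edge[1], -edge[0]])
                nrm = nrm / np.linalg.norm(nrm)
                side = (lx - a[0]) * nrm[0] + (ly - a[1]) * nrm[1]
                strip = (d <= glue) & (side * _outward_sign(corners, a_idx) > 0)
                sub[strip] = np.minimum(sub[strip], _GLUE)

            # interior (convex test: inside all 4 CCW edges)
            inside = np.ones(lx.shape, bool)
            for k in range(4):
                a, b = corners[k], corners[(k + 1) % 4]
                cross = (b[0] - a[0]) * (ly - a[1]) - (b[1] - a[1]) * (lx - a[0])
                inside &= cross >= 0
            if inside.any():
                spacing = 2.0
                lat_x0, lat_y0 = corners.min(axis=0) - 10
                lat = _ribbon_texture(scene, r)[s]
                tex = _sample_lattice(lat, lx[inside], ly[inside], lat_x0, lat_y0, spacing)
                sub[inside] = _INTERIOR + 9.0 * tex

            # dark boundary line
            dmin = np.full(lx.shape, np.inf)
            for k in range(4):
                a, b = corners[k], corners[(k + 1) % 4]
                dmin = np.minimum(dmin, _seg_dist(lx, ly, a, b))
            line = dmin <= boundary_half_um
            sub[line] = _BOUNDARY

    # persistent dark ROI structures
    for roi in scene.rois:
        for s, centre in enumerate(roi.trajectory_um):
            reach = p.roi_structure_radius_um * 2.5
            if (centre[0] + reach < x0_um or centre[1] + reach < y0_um
                    or centre[0] - reach > win_x1 or centre[1] - reach > win_y1):
                continue
            j0 = max(0, int((centre[0] - reach - x0_um) * pixels_per_um))
            j1 = min(w, int((centre[0] + reach - x0_um) * pixels_per_um) + 2)
            i0 = max(0, int((centre[1] - reach - y0_um) * pixels_per_um))
            i1 = min(h, int((centre[1] + reach - y0_um) * pixels_per_um) + 2)
            if j1 <= j0 or i1 <= i0:
                continue
            lx = X[i0:i1, j0:j1]
            ly = Y[i0:i1, j0:j1]
            sub = img[i0:i1, j0:j1]
            for (dx, dy, rad) in roi.lobes:
                d = np.hypot(lx - (centre[0] + dx), ly - (centre[1] + dy))
                soft = np.clip((d - rad) / 0.8, 0.0, 1.0)
                val = _STRUCTURE + (255.0 - _STRUCTURE) * soft
                sub[:] = np.minimum(sub, val)

    if optics_blur_um > 0:
        img = ndimage.gaussian_filter(img, optics_blur_um * pixels_per_um)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _outward_sign(corners: np.ndarray, edge_start: int) -> float:
    """Sign s.t. side*s > 0 selects the outside of the quad across this edge."""
    a = corners[edge_start]
    b = corners[(edge_start + 1) % 4]
    edge = b - a
    nrm = np.array([edge[1], -edge[0]])
    centroid = corners.mean(axis=0)
    side_c = (centroid - a) @ nrm
    return -1.0 if side_c > 0 else 1.0


def render_overview(scene: SyntheticScene, pixels_per_um: float = MAG_PIXELS_PER_UM["20x"]):
    """Full-scene 8-bit overview; returns an imageproc.OverviewImage."""
    from .imageproc import OverviewImage

    bw, bh = scene.bounds_um()
    shape = (int(np.ceil(bh * pixels_per_um)), int(np.ceil(bw * pixels_per_um)))
    img = render_region(scene, 0.0, 0.0, shape, pixels_per_um)
    return OverviewImage(pixels=img, pixel_size=1.0 / pixels_per_um, bit_depth=8)


def render_tiles(
    scene: SyntheticScene,
    pixels_per_um: float,
    tile_shape: Tuple[int, int] = (512, 512),
    overlap: float = 0.2,
    jitter_px: float = 0.0,
    seed: int = 0,
):
    """Render the scene as a row-major grid of overlapping tiles with known
    ground-truth offsets (nominal grid positions plus optional seeded jitter).

    Returns (TileGrid, true_offsets_px) where true_offsets_px[i] is the
    (row_px, col_px) of tile i's top-left corner in the monolithic raster.
    """
    from .imageproc import TileGrid

    rng = np.random.default_rng(seed)
    bw, bh = scene.bounds_um()
    full_h = int(np.ceil(bh * pixels_per_um))
    full_w = int(np.ceil(bw * pixels_per_um))
    th, tw = tile_shape
    step_y = int(round(th * (1 - overlap)))
    step_x = int(round(tw * (1 - overlap)))
    rows = max(1, int(np.ceil((full_h - th) / step_y)) + 1)
    cols = max(1, int(np.ceil((full_w - tw) / step_x)) + 1)
    tiles, offsets = [], []
    for r in range(rows):
        for c in range(cols):
            # constant pitch; edge tiles may reach past the scene into
            # background, as a real stage raster does
            oy = r * step_y
            ox = c * step_x
            if jitter_px > 0 and (r, c) != (0, 0):
                oy += int(round(rng.uniform(-jitter_px, jitter_px)))
                ox += int(round(rng.uniform(-jitter_px, jitter_px)))
                oy, ox = max(oy, 0), max(ox, 0)
            tiles.append(
                render_region(scene, ox / pixels_per_um, oy / pixels_per_um,
                              (th, tw), pixels_per_um)
            )
            offsets.append((oy, ox))
    grid = TileGrid(tiles=tiles, rows=rows, cols=cols, nominal_overlap=overlap)
    return grid, np.array(offsets, float)


# ---------------------------------------------------------------------------
# degradations (the robustness-protocol stressors)
# ---------------------------------------------------------------------------

def degrade_image(
    img: np.ndarray,
    model: str,
    *,
    sigma: float = 40.0,
    fraction: float = 0.01,
    k: int = 1,
    n: int = 10,
    truth_polys_px: Optional[Sequence[np.ndarray]] = None,
    background: float = _BG,
    seed: int = 0,
) -> np.ndarray:
    """Apply one seeded degradation to an 8-bit image.

    Models: ``gaussian`` (additive noise, std ``sigma`` gray levels),
    ``salt_pepper`` (``fraction`` of pixels flipped to 0/255),
    ``erase_corners`` / ``erase_sides`` (``k`` corners or sides per section
    replaced with background; requires ``truth_polys_px``),
    ``glue_blobs`` (``n`` dark blobs dropped on the image).
    """
    if img.dtype != np.uint8:
        raise ValueError("degradations are defined on 8-bit images")
    rng = np.random.default_rng(seed)
    out = img.astype(np.float64)

    if model == "gaussian":
        out = out + rng.normal(0.0, sigma, img.shape)
    elif model == "salt_pepper":
        u = rng.random(img.shape)
        out[u < fraction / 2] = 0.0
        out[(u >= fraction / 2) & (u < fraction)] = 255.0
    elif model in ("erase_corners", "erase_sides"):
        if truth_polys_px is None:
            raise ValueError(f"{model} requires truth_polys_px")
        if not 1 <= k <= 4:
            raise ValueError("k must be in 1..4")
        for poly in truth_polys_px:
            poly = np.asarray(poly, float)
            idx = rng.choice(4, size=k, replace=False)
            if model == "erase_corners":
                rad = 0.12 * np.linalg.norm(poly[0] - poly[2])
                for i in idx:
                    _paint_disk(out, poly[i], rad, background)
            else:
                for i in idx:
                    a, b = poly[i], poly[(i + 1) % 4]
                    # erase the middle 70% of the side
                    lo, hi = a + 0.15 * (b - a), a + 0.85 * (b - a)
                    _paint_capsule(out, lo, hi, 4.0, background)
    elif model == "glue_blobs":
        h, w = img.shape
        for _ in range(n):
            c = rng.uniform([0, 0], [w, h])
            _paint_disk(out, c, rng.uniform(10, 40), 40.0)
    else:
        raise ValueError(f"unknown degradation model {model!r}")

    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _paint_disk(img: np.ndarray, centre, radius: float, value: float) -> None:
    h, w = img.shape
    x0, y0 = centre
    j0, j1 = max(0, int(x0 - radius) - 1), min(w, int(x0 + radius) + 2)
    i0, i1 = max(0, int(y0 - radius) - 1), min(h, int(y0 + radius) + 2)
    if j1 <= j0 or i1 <= i0:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    mask = (jj - x0) ** 2 + (ii - y0) ** 2 <= radius**2
    img[i0:i1, j0:j1][mask] = value


def _paint_capsule(img: np.ndarray, a, b, half_width: float, value: float) -> None:
    h, w = img.shape
    x0 = max(0, int(min(a[0], b[0]) - half_width) - 1)
    x1 = min(w, int(max(a[0], b[0]) + half_width) + 2)
    y0 = max(0, int(min(a[1], b[1]) - half_width) - 1)
    y1 = min(h, int(max(a[1], b[1]) + half_width) + 2)
    if x1 <= x0 or y1 <= y0:
        return
    jj, ii = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    d = _seg_dist(jj.astype(float), ii.astype(float), np.asarray(a, float), np.asarray(b, float))
    img[y0:y1, x0:x1][d <= half_width] = value


# ---------------------------------------------------------------------------
# simulated microscope
# ---------------------------------------------------------------------------

class SimulatedMicroscope:
    """Software stand-in for the integrated light/electron microscope stage
    and cameras; satisfies the navigation module's MicroscopeInterface.

    The stage frame equals the scene frame (μm, origin at the overview's
    top-left) unless a calibration with a non-zero origin is supplied, in
    which case commanded stage coordinates are converted before rendering.
    Stage repeatability is modelled as seeded Gaussian jitter on the
    realised position; the commanded position is what the caller believes.
    LM defocus grows the rendering blur linearly with |focus_z - z(x,y)|;
    EM magnifications use the microscope's own autofocus, modelled as exact.
    """

    LM_MAGS = ("20x", "100x")

    def __init__(
        self,
        scene: SyntheticScene,
        pixels_per_um: Optional[Dict[str, float]] = None,
        fov_px: Optional[Dict[str, int]] = None,
        jitter_um: float = 0.0,
        seed: int = 0,
        stage_to_scene=None,
    ):
        self.scene = scene
        self.pixels_per_um = dict(pixels_per_um or MAG_PIXELS_PER_UM)
        self.fov_px = dict(fov_px or FOV_PX)
        self.jitter_um = float(jitter_um)
        self.rng = np.random.default_rng(seed)
        self.stage_to_scene = stage_to_scene or (lambda x, y: (x, y))
        self._pos = (0.0, 0.0)
        self._focus = None

    def move_to(self, x_um: float, y_um: float) -> None:
        bw, bh = self.scene.bounds_um()
        sx, sy = self.stage_to_scene(x_um, y_um)
        if not (0 <= sx <= bw and 0 <= sy <= bh):
            raise ValueError(f"stage position ({x_um:.1f}, {y_um:.1f}) μm out of scene bounds")
        self._pos = (sx, sy)

    def set_focus(self, z_um: float) -> None:
        self._focus = float(z_um)

    def acquire(self, magnification: str) -> np.ndarray:
        if magnification not in self.pixels_per_um:
            raise ValueError(f"no pixel size declared for {magnification!r}")
        ppm = self.pixels_per_um[magnification]
        n = self.fov_px.get(magnification, 384)
        cx, cy = self._pos
        if self.jitter_um > 0:
            jx, jy = self.rng.normal(0.0, self.jitter_um, 2)
            cx, cy = cx + jx, cy + jy
        x0 = cx - (n / 2) / ppm
        y0 = cy - (n / 2) / ppm
        img = render_region(self.scene, x0, y0, (n, n), ppm)
        if magnification in self.LM_MAGS and self._focus is not None:
            dz = abs(self._focus - float(self.scene.focus_z(cx, cy)))
            sigma_px = 0.5 * dz * (ppm / self.pixels_per_um["20x"])
            if sigma_px > 0.05:
                img = ndimage.gaussian_filter(img.astype(float), sigma_px)
                img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        return img
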