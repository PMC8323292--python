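"""Quadrilateral active-contour section detection on the preprocessed
edge map, ribbon-wise extension from a single user seed, and boundary-error
scoring against ground truth.

The contour is a quad-constrained snake: its energy is the negative mean
edge response sampled along the perimeter plus a shape prior that penalizes
relative deviation of side lengths and corner angles from the initial quad.
The shape prior is what lets detection survive missing corners, erased sides
and heavy noise — the quad bridges gaps where the edge response is silent.
Optimization is a greedy pattern search over nine handles (4 corners, 4 edge
midpoints, whole-quad translation) inside a 3-level block-mean image pyramid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import InvalidGeometryError, Point2D, Ribbon, SectionQuad
from .imageproc import EdgeMap

__all__ = [
    "DetectionParams",
    "FitResult",
    "DetectionResult",
    "OutOfBoundsError",
    "InsufficientContextError",
    "ConventionError",
    "fit_active_contour",
    "extend_along_ribbon",
    "detect_all_sections",
    "boundary_error",
]


class OutOfBoundsError(ValueError):
    """Initial quad lies fully outside the image."""


class InsufficientContextError(ValueError):
    """Ribbon extension needs either two detected sections or a pitch vector."""


class ConventionError(ValueError):
    """Corner-ordering conventions of two quads disagree."""


@dataclass
class DetectionParams:
    """Active-contour knobs (all in full-resolution pixels where dimensional).

    ``lambda_shape`` mixes the shape prior into the energy; ``search_radius``
    bounds how far any handle may travel per pyramid level, which also sets
    the capture range; ``reject_fraction`` scales the seed score into the
    stop threshold for ribbon extension.
    """

    lambda_shape: float = 0.3
    search_radius_px: int = 10
    reject_fraction: float = 0.4
    min_coverage: float = 0.55
    pyramid_levels: Tuple[int, ...] = (4, 2, 1)
    samples_per_edge: int = 24
    max_sections: int = 500


@dataclass
class FitResult:
    quad: SectionQuad
    score: float  # mean edge response along the perimeter, in [0, 1]
    energy: float
    coverage: float = 1.0  # fraction of perimeter samples on active response
    low_confidence: bool = False
    non_convex: bool = False


@dataclass
class DetectionResult:
    """Detected ribbons (sections in cutting order) with per-section fit
    scores and quality flags."""

    ribbons: List[Ribbon]
    scores: List[List[float]]
    flags: List[List[dict]]

    @property
    def n_sections(self) -> int:
        return sum(len(r) for r in self.ribbons)

    def to_json(self, path: str) -> None:
        d = {
            "ribbons": [
                {
                    "sections": [q.corners.tolist() for q in rib],
                    "scores": list(map(float, sc)),
                    "flags": fl,
                }
                for rib, sc, fl in zip(self.ribbons, self.scores, self.flags)
            ]
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path: str) -> "DetectionResult":
        with open(path) as fh:
            d = json.load(fh)
        ribbons, scores, flags = [], [], []
        for r in d["ribbons"]:
            ribbons.append(Ribbon(tuple(SectionQuad(np.array(c, float)) for c in r["sections"])))
            scores.append(r["scores"])
            flags.append(r["flags"])
        return cls(ribbons=ribbons, scores=scores, flags=flags)


# ---------------------------------------------------------------------------
# energy evaluation
# ---------------------------------------------------------------------------

def _block_mean_pyramid(img: np.ndarray, levels: Sequence[int]) -> Dict[int, np.ndarray]:
    """Block-mean downsampling; commutes exactly with translations that are
    multiples of the level factor, which keeps detection translation-
    equivariant."""
    out = {}
    for f in levels:
        if f == 1:
            out[1] = img
            continue
        h, w = img.shape
        ph, pw = (-h) % f, (-w) % f
        padded = np.pad(img, ((0, ph), (0, pw)))
        out[f] = padded.reshape((h + ph) // f, f, (w + pw) // f, f).mean(axis=(1, 3))
    return out


def _perimeter_points(quads: np.ndarray, k: int) -> np.ndarray:
    """(B,4,2) corner arrays -> (B, 4*k, 2) evenly spaced perimeter samples."""
    t = (np.arange(k) + 0.5) / k  # midpoint rule along each side
    a = quads  # (B,4,2)
    b = np.roll(quads, -1, axis=1)
    pts = a[:, :, None, :] * (1 - t)[None, None, :, None] + b[:, :, None, :] * t[None, None, :, None]
    return pts.reshape(quads.shape[0], -1, 2)


def _edge_score_batch(img: np.ndarray, quads: np.ndarray, k: int) -> np.ndarray:
    pts = _perimeter_points(quads, k)  # (B, N, 2) in (x, y)
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])
    vals = ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
    return vals.reshape(quads.shape[0], -1).mean(axis=1)


def _shape_dev_batch(quads: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Mean relative side-length deviation plus mean corner-angle deviation
    (radians over pi) from the reference quad."""
    def sides(q):
        d = np.roll(q, -1, axis=-2) - q
        return np.linalg.norm(d, axis=-1)  # (..., 4)

    def angles(q):
        prev = np.roll(q, 1, axis=-2) - q
        nxt = np.roll(q, -1, axis=-2) - q
        dot = (prev * nxt).sum(-1)
        nrm = np.linalg.norm(prev, axis=-1) * np.linalg.norm(nxt, axis=-1)
        return np.arccos(np.clip(dot / np.maximum(nrm, 1e-12), -1, 1))

    ls, lr = sides(quads), sides(ref)
    dev_len = (np.abs(ls - lr) / np.maximum(lr, 1e-12)).mean(axis=-1)
    dev_ang = (np.abs(angles(quads) - angles(ref)) / np.pi).mean(axis=-1)
    return dev_len + dev_ang


def _energy_batch(img, quads, ref, lam, k):
    return -_edge_score_batch(img, quads, k) + lam * _shape_dev_batch(quads, ref)


# nine handles: 4 corners, 4 edge midpoints (move both end corners), global
_HANDLES = np.zeros((9, 4, 1))
for _i in range(4):
    _HANDLES[_i, _i, 0] = 1.0
for _i in range(4):
    _HANDLES[4 + _i, _i, 0] = 1.0
    _HANDLES[4 + _i, (_i + 1) % 4, 0] = 1.0
_HANDLES[8, :, 0] = 1.0

_DIRS = np.array(
    [[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [1, -1], [-1, 1], [-1, -1]], float
)


def _pattern_search(img, quad, ref, lam, k, radius, min_step=1.0):
    """Greedy monotone pattern search; never accepts a non-improving move, so
    the returned energy is <= the starting energy."""
    cur = quad.copy()
    e_cur = float(_energy_batch(img, cur[None], ref[None], lam, k)[0])
    step = float(radius)
    # candidate displacement basis: (9 handles x 8 directions, 4, 2)
    basis = (_HANDLES[:, None, :, :] * _DIRS[None, :, None, :]).reshape(-1, 4, 2)
    while step >= min_step:
        moved = True
        while moved:
            cands = cur[None] + step * basis
            e = _energy_batch(img, cands, np.broadcast_to(ref, cands.shape), lam, k)
            i = int(np.argmin(e))
            if e[i] < e_cur - 1e-12:
                cur = cands[i]
                e_cur = float(e[i])
            else:
                moved = False
        step /= 2.0
    return cur, e_cur


def fit_active_contour(
    edge: EdgeMap,
    init: SectionQuad,
    params: Optional[DetectionParams] = None,
    _pyramid: Optional[Dict[int, np.ndarray]] = None,
) -> FitResult:
    """Snap an initial quadrilateral onto the section boundary.

    Coarse-to-fine pattern search; at the finest level the search restarts
    from whichever of {pyramid result, original init} has lower energy, so
    the fit never ends with higher energy than the init. Fits whose area
    collapses below 25% of the init are rejected and the init returned with
    a low-confidence flag.
    """
    params = params or DetectionParams()
    img = edge.response
    h, w = img.shape
    c = init.corners
    if c[:, 0].max() < 0 or c[:, 1].max() < 0 or c[:, 0].min() > w or c[:, 1].min() > h:
        raise OutOfBoundsError("initial quad lies fully outside the image")
    if not np.all(np.isfinite(img)):
        raise ValueError("edge map contains non-finite values")

    pyr = _pyramid if _pyramid is not None else _block_mean_pyramid(img, params.pyramid_levels)
    lam, k = params.lambda_shape, params.samples_per_edge
    ref_full = init.corners.astype(float)
    cur = ref_full.copy()
    for f in params.pyramid_levels:
        level_img = pyr[f]
        ref = ref_full / f
        start = cur / f
        if f == 1:
            # guarantee monotonicity w.r.t. the init at full resolution
            both = np.stack([start, ref])
            e = _energy_batch(level_img, both, np.broadcast_to(ref, both.shape), lam, k)
            start = both[int(np.argmin(e))]
        # sub-pixel steps at the finest level polish away quantization
        min_step = 0.25 if f == 1 else 1.0
        fitted, _ = _pattern_search(level_img, start, ref, lam, k,
                                    params.search_radius_px, min_step)
        cur = fitted * f

    score = float(_edge_score_batch(img, cur[None], k)[0])
    energy = float(_energy_batch(img, cur[None], ref_full[None], lam, k)[0])
    pts = _perimeter_points(cur[None], k)[0]
    vals = ndimage.map_coordinates(
        img, [pts[:, 1], pts[:, 0]], order=1, mode="constant", cval=0.0
    )
    coverage = float((vals > 0.1).mean())

    low_conf, non_convex = False, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            quad = SectionQuad(cur)
        if quad.area() < 0.25 * init.area():
            return FitResult(init, score, energy, coverage, low_confidence=True)
        non_convex = not quad.is_convex()
    except InvalidGeometryError:
        return FitResult(init, score, energy, coverage, low_confidence=True)
    return FitResult(quad, score, energy, coverage,
                     low_confidence=low_conf, non_convex=non_convex)


# ---------------------------------------------------------------------------
# ribbon extension and full-layout detection
# ---------------------------------------------------------------------------

def extend_along_ribbon(
    edge: EdgeMap,
    detected: Sequence[SectionQuad],
    pitch_vector: Optional[Tuple[float, float]] = None,
) -> SectionQuad:
    """Predict the initial quad for the next section of a ribbon.

    With two or more detected sections the predictor translates the last quad
    by the per-section centroid drift and extrapolates each corner by the
    observed per-corner drift (which captures the gradual shape change). The
    drift is averaged over up to the last three inter-section steps so that
    single-fit noise is not amplified into the next init. With exactly one
    section a user-supplied pitch vector is required.
    """
    if len(detected) == 0:
        raise InsufficientContextError("no detected sections to extend from")
    if len(detected) == 1:
        if pitch_vector is None:
            raise InsufficientContextError(
                "one detected section: supply a pitch vector to extend"
            )
        return detected[0].translated(*pitch_vector)
    last = detected[-1].corners
    k = min(3, len(detected) - 1)
    drift = (last - detected[-1 - k].corners) / k
    pred = last + drift
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return SectionQuad(pred)
        except InvalidGeometryError:
            cd = drift.mean(axis=0)
            return detected[-1].translated(cd[0], cd[1])


def _quad_in_image(quad: SectionQuad, shape) -> bool:
    h, w = shape
    c = quad.corners
    return bool(
        c[:, 0].max() > 0 and c[:, 1].max() > 0 and c[:, 0].min() < w and c[:, 1].min() < h
    )


def detect_all_sections(
    edge: EdgeMap,
    seeds: Sequence[SectionQuad],
    params: Optional[DetectionParams] = None,
    pitch_vectors: Optional[Sequence[Tuple[float, float]]] = None,
) -> DetectionResult:
    """Detect every section of every ribbon from one seed quad per ribbon.

    Each ribbon is grown in both directions from its seed — fit, extrapolate
    the next init, fit again — until the fit score falls below
    ``reject_fraction`` times the seed score or the prediction leaves the
    image. Corner ordering is inherited from the seed, so it is consistent
    across the ribbon by construction. Sections are returned in cutting
    order (the direction opposite the seed's backward growth first).
    """
    params = params or DetectionParams()
    pyr = _block_mean_pyramid(edge.response, params.pyramid_levels)
    ribbons, all_scores, all_flags = [], [], []
    for ridx, seed in enumerate(seeds):
        seed_fit = fit_active_contour(edge, seed, params, _pyramid=pyr)
        if seed_fit.low_confidence or seed_fit.score <= 0:
            warnings.warn(f"seed {ridx}: fit failed; ribbon skipped")
            continue
        threshold = params.reject_fraction * seed_fit.score
        pitch = None if pitch_vectors is None else pitch_vectors[ridx]

        def grow(context: List[SectionQuad], pv, direction: int) -> List[FitResult]:
            out: List[FitResult] = []
            for _ in range(params.max_sections):
                quads = context + [f.quad for f in out]
                if len(quads) == 1 and pv is None:
                    # bootstrap the pitch from the seed's own trapezoid axis:
                    # try a few gap factors and keep the best-scoring fit
                    fit = _bootstrap_next(edge, quads[0], params, pyr, direction)
                    if (fit is None or fit.low_confidence or fit.score < threshold
                            or fit.coverage < params.min_coverage):
                        break
                    out.append(fit)
                    continue
                try:
                    init = extend_along_ribbon(edge, quads, pv)
                except InsufficientContextError:
                    break
                if not _quad_in_image(init, edge.response.shape):
                    break
                fit = fit_active_contour(edge, init, params, _pyramid=pyr)
                if (fit.low_confidence or fit.score < threshold
                        or fit.coverage < params.min_coverage):
                    break
                # a real next section advances along the ribbon; a phantom fit
                # beyond the ribbon end slides back onto the last section
                prev_c = quads[-1].centroid.as_array()
                step = init.centroid.as_array() - prev_c
                adv = fit.quad.centroid.as_array() - prev_c
                if adv @ step < 0.25 * float(step @ step):
                    break
                out.append(fit)
            return out

        forward = grow([seed_fit.quad], None if pitch is None else tuple(pitch), +1)
        # against the cutting direction: seed the extrapolation with the
        # first forward neighbour (or the reversed pitch vector)
        back_context = ([forward[0].quad] if forward else []) + [seed_fit.quad]
        back_pitch = None if pitch is None else (-pitch[0], -pitch[1])
        backward = grow(back_context, back_pitch, -1)
        fits = list(reversed(backward)) + [seed_fit] + forward
        ribbons.append(Ribbon(tuple(f.quad for f in fits)))
        all_scores.append([f.score for f in fits])
        all_flags.append(
            [{"low_score": f.score < threshold, "non_convex": f.non_convex} for f in fits]
        )
    return DetectionResult(ribbons=ribbons, scores=all_scores, flags=all_flags)


def _bootstrap_next(edge, quad: SectionQuad, params, pyr, direction: int):
    """First extension from a lone seed: sections stack along the seed's
    leading->trailing axis; the inter-section gap is unknown, so several gap
    factors are fitted and the best-scoring result kept."""
    c = quad.corners
    axis = (c[2] + c[3]) / 2 - (c[0] + c[1]) / 2
    best = None
    for factor in (1.02, 1.06, 1.1, 1.15, 1.2, 1.3):
        step = direction * factor * axis
        init = quad.translated(step[0], step[1])
        if not _quad_in_image(init, edge.response.shape):
            continue
        fit = fit_active_contour(edge, init, params, _pyramid=pyr)
        adv = fit.quad.centroid.as_array() - quad.centroid.as_array()
        if adv @ (direction * axis) < 0.25 * float(axis @ axis):
            continue  # slid back onto the seed: not a next section
        if best is None or fit.score > best.score:
            best = fit
    return best


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def boundary_error(detected: SectionQuad, truth: SectionQuad, pixel_size: float) -> float:
    """Maximum over the four corners of the Euclidean distance to the
    corresponding ground-truth corner, scaled to micrometres.

    Both quads must use the same (counter-clockwise) ordering convention; a
    reversed orientation raises :class:`ConventionError`.
    """
    for q in (detected, truth):
        c = q.corners
        area2 = np.sum(c[:, 0] * np.roll(c[:, 1], -1) - np.roll(c[:, 0], -1) * c[:, 1])
        if area2 <= 0:
            raise ConventionError("corner ordering convention mismatch (reversed orientation)")
    d = np.linalg.norm(detected.corners - truth.corners, axis=1)
    return float(d.max() * pixel_size)
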