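"""Bilinear isoparametric (transfinite) mapping between quadrilateral sections
and the reference square, and ROI propagation between sections.

Every ultrathin section is modeled as a quadrilateral. A point inside a
section is addressed by natural coordinates (xi, eta) on the reference square
[-1, 1]^2 through the standard 4-node isoparametric shape functions

    N1 = (1-xi)(1-eta)/4,  N2 = (1+xi)(1-eta)/4,
    N3 = (1+xi)(1+eta)/4,  N4 = (1-xi)(1+eta)/4,

so that x(xi, eta) = sum_i N_i * corner_i. Because the shape functions sum to
one, the map is exactly affine-equivariant: an ROI address (xi, eta) picked in
one section lands at the geometrically corresponding spot of any other
section, however the section was sheared, scaled or rotated by cutting.

Corner ordering is cyclic counter-clockwise in image coordinates (x right,
y down), corner 1 at (-1,-1), corner 3 at (+1,+1). All quads of a ribbon must
share the ordering; the detection module enforces that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Point2D",
    "NaturalPoint",
    "SectionQuad",
    "Ribbon",
    "InvalidGeometryError",
    "ConvergenceError",
    "forward_map",
    "inverse_map",
    "propagate_roi",
    "shape_functions",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate quadrilaterals (zero/negative area, repeated or
    self-intersecting corners)."""


class ConvergenceError(RuntimeError):
    """Inverse mapping failed to converge; carries the best residual found."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Point2D:
    """A point in a Cartesian frame (overview pixels or stage micrometres;
    the frame is declared by context and never mixed within one operation)."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class NaturalPoint:
    """Section-shape-independent address on the reference square.

    For points inside a section both coordinates lie in [-1, 1]; values
    outside are legal (the map extends smoothly) but `inside` is False.
    """

    xi: float
    eta: float

    def __post_init__(self):
        if not (np.isfinite(self.xi) and np.isfinite(self.eta)):
            raise ValueError(f"non-finite natural point ({self.xi}, {self.eta})")

    @property
    def inside(self) -> bool:
        return abs(self.xi) <= 1.0 and abs(self.eta) <= 1.0


def _signed_area(corners: np.ndarray) -> float:
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclass(frozen=True)
class SectionQuad:
    """Ordered 4-corner polygon; the unit the whole pipeline navigates by.

    ``corners`` is a (4, 2) float array in fixed cyclic order with strictly
    positive signed area (counter-clockwise in image coordinates where +y
    points down).
    """

    corners: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise InvalidGeometryError(f"expected 4x2 corners, got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise InvalidGeometryError("non-finite corner coordinates")
        object.__setattr__(self, "corners", c)
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(c[i], c[j]):
                    raise InvalidGeometryError(f"corners {i} and {j} coincide")
        if _segments_cross(c[0], c[1], c[2], c[3]) or _segments_cross(c[1], c[2], c[3], c[0]):
            raise InvalidGeometryError("self-intersecting quadrilateral")
        area = _signed_area(c)
        if area <= 0:
            raise InvalidGeometryError(
                f"signed area {area:g} not positive; corner order must be "
                "counter-clockwise in image coordinates"
            )
        if not self.is_convex():
            warnings.warn(
                "non-convex quadrilateral: natural-coordinate inversion may be "
                "multivalued; the solution closest to the centroid is returned",
                stacklevel=3,
            )

    @classmethod
    def from_points(cls, pts: Iterable[Sequence[float]]) -> "SectionQuad":
        return cls(np.array([[p[0], p[1]] for p in pts], dtype=float))

    @property
    def centroid(self) -> Point2D:
        m = self.corners.mean(axis=0)
        return Point2D(float(m[0]), float(m[1]))

    def area(self) -> float:
        return _signed_area(self.corners)

    def is_convex(self) -> bool:
        c = self.corners
        cross = []
        for i in range(4):
            a, b, d = c[i], c[(i + 1) % 4], c[(i + 2) % 4]
            cross.append((b[0] - a[0]) * (d[1] - b[1]) - (b[1] - a[1]) * (d[0] - b[0]))
        cross = np.array(cross)
        return bool(np.all(cross > 0) or np.all(cross < 0))

    def diagonal(self) -> float:
        c = self.corners
        return float(max(np.linalg.norm(c[0] - c[2]), np.linalg.norm(c[1] - c[3])))

    def translated(self, dx: float, dy: float) -> "SectionQuad":
        return SectionQuad(self.corners + np.array([dx, dy]))


@dataclass(frozen=True)
class Ribbon:
    """Ordered chain of sections; order is the cutting order."""

    sections: tuple

    def __post_init__(self):
        secs = tuple(self.sections)
        if len(secs) < 1:
            raise ValueError("a ribbon holds at least one section")
        for a, b in zip(secs, secs[1:]):
            if np.allclose(a.centroid.as_array(), b.centroid.as_array()):
                raise ValueError("consecutive sections share a centroid")
        object.__setattr__(self, "sections", secs)

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self):
        return iter(self.sections)

    def __getitem__(self, i):
        return self.sections[i]


# ---------------------------------------------------------------------------
# shape functions and the forward/inverse maps
# ---------------------------------------------------------------------------

def shape_functions(xi: float, eta: float) -> np.ndarray:
    """The four bilinear shape functions N_i(xi, eta); they sum to 1."""
    return 0.25 * np.array(
        [
            (1 - xi) * (1 - eta),
            (1 + xi) * (1 - eta),
            (1 + xi) * (1 + eta),
            (1 - xi) * (1 + eta),
        ]
    )


def forward_map(quad: SectionQuad, p: NaturalPoint) -> Point2D:
    """Map natural coordinates on the reference square to Cartesian
    coordinates inside (or, extrapolating, outside) ``quad``."""
    n = shape_functions(p.xi, p.eta)
    xy = n @ quad.corners
    return Point2D(float(xy[0]), float(xy[1]))


def _jacobian(quad: SectionQuad, xi: float, eta: float) -> np.ndarray:
    c = quad.corners
    dn_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dn_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    return np.column_stack([dn_dxi @ c, dn_deta @ c]).T  # rows: d(x,y)/dxi, d(x,y)/deta


def _newton(quad: SectionQuad, target: np.ndarray, x0: np.ndarray,
            tol: float, max_iter: int):
    """Damped Newton on the 2x2 bilinear system; returns (xi_eta, residual)."""
    q = x0.astype(float).copy()
    best_q, best_r = q.copy(), np.inf
    for _ in range(max_iter):
        xy = shape_functions(q[0], q[1]) @ quad.corners
        r = xy - target
        rn = float(np.linalg.norm(r))
        if rn < best_r:
            best_r, best_q = rn, q.copy()
        if rn <= tol:
            return q, rn
        jac = _jacobian(quad, q[0], q[1]).T  # d(x,y)/d(xi,eta)
        det = jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0]
        if abs(det) < 1e-300:
            break
        step = np.linalg.solve(jac, -r)
        # damp: halve until the residual decreases (bilinear => quadratic,
        # full steps almost always fine for convex quads)
        lam = 1.0
        for _ in range(20):
            q_new = q + lam * step
            xy_new = shape_functions(q_new[0], q_new[1]) @ quad.corners
            if np.linalg.norm(xy_new - target) < rn:
                break
            lam *= 0.5
        else:
            break
        q = q + lam * step
    return best_q, best_r


def inverse_map(quad: SectionQuad, p: Point2D, tol: float = 1e-9,
                max_iter: int = 50) -> NaturalPoint:
    """Invert the bilinear map: find (xi, eta) with forward_map == ``p``.

    Damped Newton started at the element centre (0, 0); if that stalls, the
    best seed of a coarse 41x41 grid over [-1,1]^2 restarts Newton. For
    non-convex (but simple) quads the inverse may be multivalued; the branch
    reachable from the centroid is returned.

    Raises :class:`ConvergenceError` (carrying the best residual) if no root
    is found to ``tol``.
    """
    target = p.as_array()
    q, r = _newton(quad, target, np.zeros(2), tol, max_iter)
    if r > tol:
        # coarse grid seed, then restart
        g = np.linspace(-1, 1, 41)
        gx, gy = np.meshgrid(g, g)
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
        n = 0.25 * np.stack(
            [
                (1 - pts[:, 0]) * (1 - pts[:, 1]),
                (1 + pts[:, 0]) * (1 - pts[:, 1]),
                (1 + pts[:, 0]) * (1 + pts[:, 1]),
                (1 - pts[:, 0]) * (1 + pts[:, 1]),
            ],
            axis=1,
        )
        d = np.linalg.norm(n @ quad.corners - target, axis=1)
        seed = pts[int(np.argmin(d))]
        q2, r2 = _newton(quad, target, seed, tol, max_iter)
        if r2 < r:
            q, r = q2, r2
    if r > tol:
        raise ConvergenceError(
            f"inverse map did not converge (best residual {r:.3g})", residual=r
        )
    return NaturalPoint(float(q[0]), float(q[1]))


def propagate_roi(quad_i: SectionQuad, quad_j: SectionQuad, p_i: Point2D) -> Point2D:
    """Carry a point from section i to section j through natural coordinates.

    The ROI position in section i is expressed as (xi, eta), then evaluated
    on section j's corners; this is how an ROI picked once is predicted in
    every other section of the ribbon.
    """
    nat = inverse_map(quad_i, p_i)
    if not nat.inside:
        warnings.warn(
            f"point ({p_i.x:g}, {p_i.y:g}) lies outside its section "
            f"(xi={nat.xi:.3f}, eta={nat.eta:.3f}); extrapolating",
            stacklevel=2,
        )
    return forward_map(quad_j, nat)
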