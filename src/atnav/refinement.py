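"""Stepwise refinement: register acquired stacks and feed the transforms
back into the navigation plan.

At each magnification rung the per-section frames of one ROI are aligned by
phase correlation, chained pairwise (section k against k-1, because
neighbouring sections resemble each other most) and accumulated to the first
frame. The accumulated shift of section k measures how far the ROI drifted
from where navigation put it, relative to the reference section; adding it
to the stage targets of all higher magnifications corrects the navigation
before the next, smaller field of view is acquired. Corrections are logged
per section as (dx, dy, sqrt(dx^2+dy^2)) μm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .config import MAG_LADDER
from .navigation import ImageStack, NavigationPlan, PlanEntry  # re-exported container

__all__ = [
    "RegistrationResult",
    "CorrespondenceError",
    "register_stack",
    "refine_plan",
    "corrections_table",
    "write_corrections_csv",
]


class CorrespondenceError(ValueError):
    """Registration frames do not correspond 1:1 to plan entries."""


@dataclass
class RegistrationResult:
    """Per-frame content displacement relative to frame 0.

    ``shifts[k]`` is (dx, dy) in pixels: the apparent position of the scene
    content in frame k minus its position in frame 0 (so shifts[0] == 0).
    ``rotations`` in degrees (zero in translation mode); ``confidence`` is
    the correlation peak ratio of each chained pair (1.0 for the reference).
    """

    shifts: np.ndarray  # (n, 2) float, (dx, dy) px
    rotations: np.ndarray  # (n,) degrees
    confidence: np.ndarray  # (n,)
    roi_id: str = ""
    mag: str = ""
    sections: List[int] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.shifts[0], 0):
            raise ValueError("reference frame shift must be (0, 0)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("non-finite shift")


def _peak_ratio(a: np.ndarray, b: np.ndarray) -> float:
    """Ratio of the phase-correlation peak to the surface RMS — near 1 for
    featureless pairs, large for a well-defined registration."""
    fa, fb = np.fft.rfft2(a), np.fft.rfft2(b)
    cross = fa * np.conj(fb)
    denom = np.abs(cross)
    cross = np.where(denom > 1e-12, cross / np.maximum(denom, 1e-12), 0)
    surf = np.abs(np.fft.irfft2(cross, s=a.shape))
    rms = surf.std()
    if rms <= 0:
        return 0.0
    return float(surf.max() / rms)


def _register_pair(ref: np.ndarray, mov: np.ndarray, upsample: int) -> Tuple[np.ndarray, float]:
    """(dx, dy) content displacement of ``mov`` relative to ``ref``."""
    if ref.std() < 1e-9 or mov.std() < 1e-9:
        return np.zeros(2), 0.0
    # amplitude-weighted correlation (no spectral whitening): the tracked
    # high-contrast structure dominates the peak, so registration follows
    # the ROI rather than the surrounding section texture, which drifts
    # relative to the ROI from section to section
    shift, _, _ = phase_cross_correlation(
        ref.astype(float), mov.astype(float), upsample_factor=upsample,
        normalization=None,
    )
    # phase_cross_correlation returns the (row, col) translation that moves
    # `mov` onto `ref`; content displacement is its negation, as (dx, dy)
    d = -shift
    conf = _peak_ratio(ref.astype(float), mov.astype(float))
    return np.array([d[1], d[0]]), conf


def register_stack(
    stack: ImageStack,
    mode: str = "translation",
    upsample_factor: int = 10,
) -> RegistrationResult:
    """Chained sub-pixel registration of a per-section stack.

    Each frame is registered against its predecessor and the pairwise
    displacements accumulated to frame 0. ``mode='rigid'`` adds a coarse
    rotation search (±5° in 0.5° steps) before the translation estimate.
    Featureless frames contribute zero shift with zero confidence.
    """
    if mode not in ("translation", "rigid"):
        raise ValueError("mode must be translation|rigid")
    n = len(stack.frames)
    if n < 2:
        raise ValueError("need at least two frames to register")
    shifts = np.zeros((n, 2))
    rots = np.zeros(n)
    conf = np.full(n, np.inf)
    conf[0] = np.inf
    acc = np.zeros(2)
    acc_rot = 0.0
    for k in range(1, n):
        ref = np.asarray(stack.frames[k - 1], float)
        mov = np.asarray(stack.frames[k], float)
        rot_k = 0.0
        if mode == "rigid":
            best = (None, 0.0, 0.0)
            for ang in np.arange(-5.0, 5.0 + 1e-9, 0.5):
                cand = ndimage.rotate(mov, -ang, reshape=False, order=1, mode="nearest") if ang else mov
                r = _peak_ratio(ref, cand)
                if r > best[1]:
                    best = (cand, r, ang)
            mov, _, rot_k = best
        d, c = _register_pair(ref, mov, upsample_factor)
        acc = acc + d
        acc_rot += rot_k
        shifts[k] = acc
        rots[k] = acc_rot
        conf[k] = c
    conf[0] = float(np.max(conf[1:])) if n > 1 else 1.0
    sections = [e.section for e in stack.entries] if stack.entries else list(range(n))
    return RegistrationResult(
        shifts=shifts, rotations=rots, confidence=conf,
        roi_id=stack.roi_id, mag=stack.mag, sections=sections,
    )


# ---------------------------------------------------------------------------
# feeding corrections back into the plan
# ---------------------------------------------------------------------------

def refine_plan(
    plan: NavigationPlan,
    reg: RegistrationResult,
    stack_pixel_size: float,
    next_mag: str,
    ladder: Tuple[str, ...] = MAG_LADDER,
) -> NavigationPlan:
    """Apply registration shifts to the stage targets of every magnification
    at or above ``next_mag`` for the registered ROI.

    The correction for section k is axis_signs ⊙ shifts[k] · pixel_size μm:
    where registration found the content displaced, the stage target moves
    with it. Corrections are additive, zero shifts leave the plan unchanged,
    and rungs below ``next_mag`` (already acquired) are never touched.
    """
    if next_mag not in ladder:
        raise ValueError(f"unknown magnification {next_mag!r}")
    signs = plan.calibration.axis_signs if plan.calibration else (1, 1)
    level = ladder.index(next_mag)
    upgraded = {m for m in ladder[level:]}

    by_section = dict(zip(reg.sections, range(len(reg.sections))))
    target_entries = [
        e for e in plan.entries if e.roi_id == reg.roi_id and e.mag in upgraded
    ]
    target_sections = {e.section for e in target_entries}
    if not target_sections <= set(reg.sections):
        missing = sorted(target_sections - set(reg.sections))
        raise CorrespondenceError(
            f"plan sections {missing} have no registered frame for ROI {reg.roi_id!r}"
        )

    new_entries = []
    for e in plan.entries:
        if e.roi_id == reg.roi_id and e.mag in upgraded:
            k = by_section[e.section]
            dx_um = signs[0] * reg.shifts[k, 0] * stack_pixel_size
            dy_um = signs[1] * reg.shifts[k, 1] * stack_pixel_size
            e = PlanEntry(e.roi_id, e.section, e.mag,
                          e.x_um + dx_um, e.y_um + dy_um, e.z_um, e.status)
        new_entries.append(e)
    return NavigationPlan(
        entries=new_entries,
        calibration=plan.calibration,
        focus_anchors=plan.focus_anchors,
        rois=plan.rois,
    )


def corrections_table(
    reg: RegistrationResult, stack_pixel_size: float, axis_signs=(1, 1)
) -> List[Tuple[int, float, float, float]]:
    """(section, dx_um, dy_um, magnitude_um) per registered section; the
    magnitude is sqrt(dx^2 + dy^2)."""
    rows = []
    for k, sec in enumerate(reg.sections):
        dx = axis_signs[0] * reg.shifts[k, 0] * stack_pixel_size
        dy = axis_signs[1] * reg.shifts[k, 1] * stack_pixel_size
        rows.append((sec, float(dx), float(dy), float(np.hypot(dx, dy))))
    return rows


def write_corrections_csv(path: str, rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["section", "dx_um", "dy_um", "magnitude_um"])
        for r in rows:
            w.writerow([r[0], f"{r[1]:.4f}", f"{r[2]:.4f}", f"{r[3]:.4f}"])
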