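"""Stage calibration, ROI definition, navigation-plan generation and the
acquisition loop.

The overview image anchors the coordinate system: the stage is "calibrated"
by zeroing it at a chosen overview pixel (in practice a section corner near
the field-of-view centre), after which every overview pixel maps to absolute
stage micrometres. An ROI is clicked once, in one section; its natural
coordinates inside that section are computed and the transfinite map predicts
its position in every other detected section of the ribbon. The navigation
plan lists one stage target per (ROI, section, magnification) with a focus
value, and is persisted after every acquisition so an interrupted run resumes
exactly where it stopped.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Protocol, Sequence, Tuple, Union

import numpy as np

from .config import FOV_PX, MAG_PIXELS_PER_UM
from .detection import DetectionResult
from .focusmap import FocusMap, interpolate_focus
from .geometry import NaturalPoint, Point2D, SectionQuad, forward_map, inverse_map

__all__ = [
    "StageCalibration",
    "ROI",
    "PlanEntry",
    "NavigationPlan",
    "ImageStack",
    "MicroscopeInterface",
    "AcquisitionError",
    "PlanRangeError",
    "calibrate_stage",
    "build_plan",
    "acquire_stack",
]


class PlanRangeError(IndexError):
    """Requested section range exceeds what detection found."""


class AcquisitionError(RuntimeError):
    """One or more plan entries failed; carries the stacks acquired so far."""

    def __init__(self, message: str, stacks=None):
        super().__init__(message)
        self.stacks = stacks or {}


@dataclass(frozen=True)
class StageCalibration:
    """Pixel <-> stage map: s = axis_signs * (p - origin_px) * pixel_size.

    ``origin_px`` is the overview pixel declared to be stage (0, 0);
    ``pixel_size`` is μm/px of the overview; ``axis_signs`` flips axes for
    stages whose +x/+y do not match image right/down.
    """

    origin_px: Tuple[float, float]
    pixel_size: float
    axis_signs: Tuple[int, int] = (1, 1)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def pixel_to_stage(self, p: Point2D) -> Point2D:
        sx = self.axis_signs[0] * (p.x - self.origin_px[0]) * self.pixel_size
        sy = self.axis_signs[1] * (p.y - self.origin_px[1]) * self.pixel_size
        return Point2D(sx, sy)

    def stage_to_pixel(self, s: Point2D) -> Point2D:
        px = self.origin_px[0] + self.axis_signs[0] * s.x / self.pixel_size
        py = self.origin_px[1] + self.axis_signs[1] * s.y / self.pixel_size
        return Point2D(px, py)


def calibrate_stage(
    origin_px: Point2D,
    pixel_size: float,
    axis_signs: Tuple[int, int] = (1, 1),
) -> StageCalibration:
    """Declare an overview pixel to be the stage origin (0, 0)."""
    return StageCalibration(
        origin_px=(origin_px.x, origin_px.y),
        pixel_size=float(pixel_size),
        axis_signs=tuple(axis_signs),
    )


@dataclass
class ROI:
    """A region of interest defined by one click in one section.

    ``natural`` is the section-independent address derived from the anchor
    section's quad; ``fov_per_mag`` optionally records the field of view (μm)
    wanted at each magnification.
    """

    id: str
    ribbon: int
    anchor_section: int
    anchor_point: Point2D  # overview pixels
    natural: Optional[NaturalPoint] = None
    fov_per_mag: Dict[str, float] = field(default_factory=dict)


@dataclass
class PlanEntry:
    roi_id: str
    section: int
    mag: str
    x_um: float
    y_um: float
    z_um: float
    status: str = "pending"  # pending | done | failed

    def key(self) -> Tuple[str, int, str]:
        return (self.roi_id, self.section, self.mag)


@dataclass
class NavigationPlan:
    """The resumable navigation file: the single source of truth for a run."""

    entries: List[PlanEntry]
    calibration: Optional[StageCalibration] = None
    focus_anchors: Optional[np.ndarray] = None
    rois: List[ROI] = field(default_factory=list)

    def __post_init__(self):
        keys = [e.key() for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (roi, section, magnification) plan entry")

    def pending(self) -> List[PlanEntry]:
        return [e for e in self.entries if e.status == "pending"]

    def for_roi_mag(self, roi_id: str, mag: str) -> List[PlanEntry]:
        es = [e for e in self.entries if e.roi_id == roi_id and e.mag == mag]
        return sorted(es, key=lambda e: e.section)

    # -- serialization (documented schema, round-trip tested) ---------------

    def to_dict(self) -> dict:
        return {
            "calibration": None
            if self.calibration is None
            else {
                "origin_px": list(self.calibration.origin_px),
                "pixel_size": self.calibration.pixel_size,
                "axis_signs": list(self.calibration.axis_signs),
            },
            "focus_anchors": None
            if self.focus_anchors is None
            else np.asarray(self.focus_anchors).tolist(),
            "rois": [
                {
                    "id": r.id,
                    "ribbon": r.ribbon,
                    "anchor_section": r.anchor_section,
                    "anchor_point": [r.anchor_point.x, r.anchor_point.y],
                    "natural": None if r.natural is None else [r.natural.xi, r.natural.eta],
                    "fov_per_mag": r.fov_per_mag,
                }
                for r in self.rois
            ],
            "entries": [
                {
                    "roi_id": e.roi_id,
                    "section": e.section,
                    "mag": e.mag,
                    "x_um": e.x_um,
                    "y_um": e.y_um,
                    "z_um": e.z_um,
                    "status": e.status,
                }
                for e in self.entries
            ],
        }

    def save(self, path: str) -> None:
        # write-then-rename so an interrupted save never truncates the plan
        d = os.path.dirname(os.path.abspath(path))
        fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        with os.fdopen(fd, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        os.replace(tmp, path)

    @classmethod
    def from_dict(cls, d: dict) -> "NavigationPlan":
        try:
            cal = None
            if d.get("calibration") is not None:
                c = d["calibration"]
                cal = StageCalibration(
                    origin_px=tuple(c["origin_px"]),
                    pixel_size=c["pixel_size"],
                    axis_signs=tuple(c["axis_signs"]),
                )
            fa = d.get("focus_anchors")
            rois = [
                ROI(
                    id=r["id"],
                    ribbon=r["ribbon"],
                    anchor_section=r["anchor_section"],
                    anchor_point=Point2D(*r["anchor_point"]),
                    natural=None if r.get("natural") is None else NaturalPoint(*r["natural"]),
                    fov_per_mag=dict(r.get("fov_per_mag", {})),
                )
                for r in d.get("rois", [])
            ]
            entries = [
                PlanEntry(
                    roi_id=e["roi_id"],
                    section=int(e["section"]),
                    mag=e["mag"],
                    x_um=float(e["x_um"]),
                    y_um=float(e["y_um"]),
                    z_um=float(e["z_um"]),
                    status=e["status"],
                )
                for e in d["entries"]
            ]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed navigation plan: {exc}") from exc
        return cls(
            entries=entries,
            calibration=cal,
            focus_anchors=None if fa is None else np.asarray(fa, float),
            rois=rois,
        )

    @classmethod
    def load(cls, path: str) -> "NavigationPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class ImageStack:
    """Per-section frames of one ROI at one magnification, in section order,
    with the plan entries that produced them."""

    frames: List[np.ndarray]
    pixel_size: float  # μm/px
    roi_id: str
    mag: str
    entries: List[PlanEntry] = field(default_factory=list)

    def __post_init__(self):
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("stack frames must share one shape")

    def __len__(self) -> int:
        return len(self.frames)


class MicroscopeInterface(Protocol):
    """Hardware abstraction satisfied in this repository by the simulator."""

    def move_to(self, x_um: float, y_um: float) -> None: ...

    def set_focus(self, z_um: float) -> None: ...

    def acquire(self, magnification: str) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------

def build_plan(
    rois: Sequence[ROI],
    detection: DetectionResult,
    cal: StageCalibration,
    focus: Optional[FocusMap],
    magnifications: Union[str, Sequence[str]] = "20x",
    start_section: int = 0,
    n_sections: Optional[int] = None,
    order: str = "roi",
) -> NavigationPlan:
    """Generate stage targets for every (ROI, section, magnification).

    Each ROI's anchor point is converted once into natural coordinates via
    its anchor section's quad, then evaluated on every requested section's
    quad and calibrated into stage micrometres; the focus surface supplies z.
    ROI predictions are fully independent of one another, so a multi-ROI
    plan equals the concatenation of single-ROI plans. ``order`` = "roi"
    iterates sections within each ROI; "section" interleaves ROIs per
    section.
    """
    if isinstance(magnifications, str):
        magnifications = [magnifications]
    if order not in ("roi", "section"):
        raise ValueError("order must be 'roi' or 'section'")

    per_roi: Dict[str, List[PlanEntry]] = {}
    resolved: List[ROI] = []
    for roi in rois:
        quads = detection.ribbons[roi.ribbon]
        n = n_sections if n_sections is not None else len(quads) - start_section
        if start_section < 0 or start_section + n > len(quads):
            raise PlanRangeError(
                f"sections [{start_section}, {start_section + n}) requested; "
                f"ribbon {roi.ribbon} has {len(quads)} detected"
            )
        anchor_quad = quads[roi.anchor_section]
        nat = inverse_map(anchor_quad, roi.anchor_point)
        if not nat.inside:
            warnings.warn(f"ROI {roi.id}: anchor point outside its section")
        roi = replace(roi, natural=nat)
        resolved.append(roi)
        entries = []
        for k in range(start_section, start_section + n):
            p_px = forward_map(quads[k], nat)
            s = cal.pixel_to_stage(p_px)
            if focus is not None and len(focus):
                z = interpolate_focus(focus, s.x, s.y).z
            else:
                z = 0.0
            for mag in magnifications:
                entries.append(
                    PlanEntry(roi_id=roi.id, section=k, mag=mag,
                              x_um=s.x, y_um=s.y, z_um=float(z))
                )
        per_roi[roi.id] = entries

    if order == "roi":
        all_entries = [e for r in resolved for e in per_roi[r.id]]
    else:
        all_entries = sorted(
            (e for r in resolved for e in per_roi[r.id]),
            key=lambda e: (e.section, e.roi_id, e.mag),
        )
    return NavigationPlan(
        entries=all_entries,
        calibration=cal,
        focus_anchors=None if focus is None else focus.anchors.copy(),
        rois=resolved,
    )


# ---------------------------------------------------------------------------
# acquisition loop
# ---------------------------------------------------------------------------

def acquire_stack(
    plan: NavigationPlan,
    scope: MicroscopeInterface,
    settle_s: float = 2.0,
    pixels_per_um: Optional[Dict[str, float]] = None,
    magnifications: Optional[Sequence[str]] = None,
    persist_path: Optional[str] = None,
) -> Dict[Tuple[str, str], ImageStack]:
    """Execute every pending plan entry (optionally restricted to some
    magnifications) and collect the frames into one stack per (ROI, mag).

    Entries run in plan order (section order within each ROI); after every
    entry the status is updated and, when ``persist_path`` is given, the plan
    re-saved so an interrupted acquisition resumes with only the pending
    entries. A scope failure marks the entry failed and the loop continues;
    a summary :class:`AcquisitionError` carrying the completed stacks is
    raised at the end. ``settle_s`` is recorded as the commanded settle wait
    between stage moves (the simulator does not advance wall-clock time).
    """
    ppm = dict(pixels_per_um or MAG_PIXELS_PER_UM)
    stacks: Dict[Tuple[str, str], ImageStack] = {}
    failures = []
    for entry in plan.entries:
        if entry.status != "pending":
            continue
        if magnifications is not None and entry.mag not in magnifications:
            continue
        try:
            scope.move_to(entry.x_um, entry.y_um)
            scope.set_focus(entry.z_um)
            frame = scope.acquire(entry.mag)
            entry.status = "done"
        except Exception as exc:  # noqa: BLE001 - scope errors must not stop the run
            entry.status = "failed"
            failures.append((entry.key(), str(exc)))
            if persist_path:
                plan.save(persist_path)
            continue
        key = (entry.roi_id, entry.mag)
        if key not in stacks:
            stacks[key] = ImageStack(
                frames=[], pixel_size=1.0 / ppm[entry.mag],
                roi_id=entry.roi_id, mag=entry.mag,
            )
        stacks[key].frames.append(frame)
        stacks[key].entries.append(entry)
        if persist_path:
            plan.save(persist_path)
    if failures:
        raise AcquisitionError(
            f"{len(failures)} plan entr{'y' if len(failures) == 1 else 'ies'} failed: "
            + "; ".join(f"{k}: {m}" for k, m in failures[:5]),
            stacks=stacks,
        )
    return stacks
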