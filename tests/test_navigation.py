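"""Stage calibration, plan generation, acquisition loop and plan file."""

import numpy as np
import pytest

from atnav.detection import DetectionResult
from atnav.focusmap import FocusMap
from atnav.geometry import Point2D, Ribbon, SectionQuad
from atnav.navigation import (
    ROI,
    NavigationPlan,
    PlanEntry,
    PlanRangeError,
    acquire_stack,
    build_plan,
    calibrate_stage,
)
from atnav.synthetic import SimulatedMicroscope

PPM = 2.96


class TestCalibration:
    def test_origin_maps_to_zero(self):
        cal = calibrate_stage(Point2D(100, 200), 1 / PPM)
        s = cal.pixel_to_stage(Point2D(100, 200))
        assert s.x == 0.0 and s.y == 0.0

    def test_296_pixels_is_100_um(self):
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM, (1, 1))
        s = cal.pixel_to_stage(Point2D(296, 0))
        assert s.x == pytest.approx(100.0, abs=1e-9)
        assert s.y == 0.0

    def test_round_trip_identity(self):
        cal = calibrate_stage(Point2D(40, 60), 1 / PPM, (1, -1))
        p = Point2D(123.4, 567.8)
        back = cal.pixel_to_stage(cal.stage_to_pixel(p))
        assert back.x == pytest.approx(p.x, abs=1e-9)
        assert back.y == pytest.approx(p.y, abs=1e-9)


def _toy_detection(n=5, pitch=(0.0, 225.0)):
    base = SectionQuad.from_points([(50, 30), (370, 30), (360, 230), (60, 230)])
    quads = [base.translated(k * pitch[0], k * pitch[1]) for k in range(n)]
    return DetectionResult(ribbons=[Ribbon(tuple(quads))],
                           scores=[[1.0] * n], flags=[[{}] * n])


class TestBuildPlan:
    def test_cardinality(self):
        det = _toy_detection(5)
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM)
        roi = ROI("r", 0, 0, Point2D(200, 120))
        plan = build_plan([roi], det, cal, None, magnifications=["20x", "100x"])
        assert len(plan.entries) == 5 * 2
        keys = {(e.roi_id, e.section, e.mag) for e in plan.entries}
        assert len(keys) == 10

    def test_translated_sections_give_centroid_targets(self):
        """An ROI at a section centre, sections all identical translates:
        targets are exactly the section centroids in stage μm."""
        det = _toy_detection(4)
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM)
        centroid0 = det.ribbons[0][0].centroid
        roi = ROI("r", 0, 0, centroid0)
        plan = build_plan([roi], det, cal, None, magnifications="20x")
        for k, e in enumerate(plan.for_roi_mag("r", "20x")):
            c = det.ribbons[0][k].centroid
            assert e.x_um == pytest.approx(c.x / PPM, abs=1e-6)
            assert e.y_um == pytest.approx(c.y / PPM, abs=1e-6)

    def test_multiplexing_equals_independent_plans(self):
        det = _toy_detection(4)
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM)
        r1 = ROI("a", 0, 0, Point2D(150, 100))
        r2 = ROI("b", 0, 1, Point2D(250, 330))
        both = build_plan([r1, r2], det, cal, None)
        solo1 = build_plan([r1], det, cal, None)
        solo2 = build_plan([r2], det, cal, None)
        for e_both, e_solo in zip(both.for_roi_mag("a", "20x"), solo1.for_roi_mag("a", "20x")):
            assert (e_both.x_um, e_both.y_um) == (e_solo.x_um, e_solo.y_um)
        for e_both, e_solo in zip(both.for_roi_mag("b", "20x"), solo2.for_roi_mag("b", "20x")):
            assert (e_both.x_um, e_both.y_um) == (e_solo.x_um, e_solo.y_um)

    def test_range_error(self):
        det = _toy_detection(3)
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM)
        roi = ROI("r", 0, 0, Point2D(200, 120))
        with pytest.raises(PlanRangeError):
            build_plan([roi], det, cal, None, n_sections=10)

    def test_focus_from_map(self):
        det = _toy_detection(3)
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM)
        fm = FocusMap([[0, 0, 50.0], [500, 0, 50.0], [0, 500, 50.0], [500, 500, 50.0]])
        roi = ROI("r", 0, 0, Point2D(200, 120))
        plan = build_plan([roi], det, cal, fm)
        assert all(e.z_um == pytest.approx(50.0, abs=1e-6) for e in plan.entries)

    def test_deterministic(self):
        det = _toy_detection(4)
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM)
        roi = ROI("r", 0, 0, Point2D(200, 120))
        a = build_plan([roi], det, cal, None)
        b = build_plan([roi], det, cal, None)
        assert a.to_dict() == b.to_dict()


class TestPlanFile:
    def _plan(self):
        entries = [
            PlanEntry("r", 0, "20x", 10.0, 20.0, 50.0, "done"),
            PlanEntry("r", 1, "20x", 11.0, 96.0, 50.1, "pending"),
            PlanEntry("r", 1, "100x", 11.0, 96.0, 50.1, "failed"),
        ]
        cal = calibrate_stage(Point2D(5, 6), 1 / PPM, (1, -1))
        return NavigationPlan(entries=entries, calibration=cal,
                              focus_anchors=np.array([[0.0, 0.0, 50.0]]))

    def test_round_trip_field_for_field(self, tmp_path):
        plan = self._plan()
        p = tmp_path / "plan.json"
        plan.save(str(p))
        back = NavigationPlan.load(str(p))
        assert back.to_dict() == plan.to_dict()

    def test_statuses_preserved(self, tmp_path):
        plan = self._plan()
        p = tmp_path / "plan.json"
        plan.save(str(p))
        back = NavigationPlan.load(str(p))
        assert [e.status for e in back.entries] == ["done", "pending", "failed"]

    def test_truncated_file_raises(self, tmp_path):
        from atnav.cli import roundtrip_plan

        p = tmp_path / "plan.json"
        self._plan().save(str(p))
        txt = p.read_text()
        p.write_text(txt[: len(txt) // 2])
        with pytest.raises(ValueError):
            roundtrip_plan(str(p))

    def test_duplicate_entries_rejected(self):
        e = PlanEntry("r", 0, "20x", 0, 0, 0)
        with pytest.raises(ValueError, match="duplicate"):
            NavigationPlan(entries=[e, PlanEntry("r", 0, "20x", 1, 1, 1)])


class TestAcquireStack:
    def _setup(self, small_scene):
        quads = [SectionQuad(c * PPM) for c in small_scene.ribbons_um[0]]
        det = DetectionResult(ribbons=[Ribbon(tuple(quads))],
                              scores=[[1.0] * len(quads)], flags=[[{}] * len(quads)])
        cal = calibrate_stage(Point2D(0, 0), 1 / PPM)
        anchor = small_scene.rois[0].trajectory_um[0] * PPM
        roi = ROI("r", 0, 0, Point2D(*anchor))
        w, h = small_scene.bounds_um()
        fm = FocusMap([[x, y, float(small_scene.focus_z(x, y))]
                       for x in (0, w) for y in (0, h)])
        plan = build_plan([roi], det, cal, fm, magnifications=["100x"])
        scope = SimulatedMicroscope(small_scene, jitter_um=0.0, seed=0)
        return plan, scope

    def test_perfect_simulator_centres_roi(self, small_scene):
        """With an exact plan and no jitter, each frame holds the tracked
        structure near the frame centre (within the central 10% + the
        bounded per-section trajectory drift)."""
        plan, scope = self._setup(small_scene)
        stacks = acquire_stack(plan, scope)
        st = stacks[("r", "100x")]
        traj = small_scene.rois[0].trajectory_um
        n = st.frames[0].shape[0]
        for k, (frame, e) in enumerate(zip(st.frames, st.entries)):
            dark = frame < 80
            assert dark.any()
            iy, ix = np.nonzero(dark)
            # the structure sits at (trajectory - commanded target) from the
            # frame centre; the dark-mass centroid must land there
            exp = (traj[k] - [e.x_um, e.y_um]) * 15.38
            err = np.hypot(iy.mean() - ((n - 1) / 2 + exp[1]),
                           ix.mean() - ((n - 1) / 2 + exp[0]))
            assert err <= 0.05 * n

    def test_resume_acquires_only_pending(self, small_scene):
        plan, scope = self._setup(small_scene)
        half = len(plan.entries) // 2
        for e in plan.entries[:half]:
            e.status = "done"
        stacks = acquire_stack(plan, scope)
        st = stacks[("r", "100x")]
        assert len(st) == len(plan.entries) - half
        assert all(e.status == "done" for e in plan.entries)

    def test_empty_plan_is_noop(self, small_scene):
        plan, scope = self._setup(small_scene)
        for e in plan.entries:
            e.status = "done"
        stacks = acquire_stack(plan, scope)
        assert stacks == {}

    def test_failed_entry_continues_and_summarises(self, small_scene):
        from atnav.navigation import AcquisitionError

        plan, scope = self._setup(small_scene)
        plan.entries[2].x_um = -1e6  # drive out of bounds
        with pytest.raises(AcquisitionError) as exc:
            acquire_stack(plan, scope)
        assert plan.entries[2].status == "failed"
        done = [e for e in plan.entries if e.status == "done"]
        assert len(done) == len(plan.entries) - 1
        assert len(exc.value.stacks[("r", "100x")]) == len(done)

    def test_plan_persisted_during_run(self, small_scene, tmp_path):
        plan, scope = self._setup(small_scene)
        path = tmp_path / "plan.json"
        acquire_stack(plan, scope, persist_path=str(path))
        back = NavigationPlan.load(str(path))
        assert all(e.status == "done" for e in back.entries)
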