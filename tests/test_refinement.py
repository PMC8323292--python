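"""Stack registration and the registration-feedback correction of the plan."""

import numpy as np
import pytest
from scipy import ndimage

from atnav.navigation import ImageStack, NavigationPlan, PlanEntry
from atnav.refinement import (
    CorrespondenceError,
    corrections_table,
    refine_plan,
    register_stack,
)


def _stack(frames, roi="r", mag="20x", pixel_size=1 / 2.96, sections=None):
    entries = [
        PlanEntry(roi, s, mag, 0.0, 0.0, 0.0)
        for s in (sections or range(len(frames)))
    ]
    return ImageStack(frames=list(frames), pixel_size=pixel_size,
                      roi_id=roi, mag=mag, entries=entries)


def _textured(shape=(128, 128), seed=0):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.standard_normal(shape), 3)
    return (120 + 400 * img).clip(0, 255)


class TestRegisterStack:
    def test_identical_frames_zero_shift(self):
        f = _textured()
        reg = register_stack(_stack([f, f, f]))
        np.testing.assert_allclose(reg.shifts, 0, atol=1e-6)

    def test_integer_shift_recovered(self):
        """Frame 1 = frame 0 rolled by (dx=7, dy=-3): recovered within
        0.5 px (synthetic shift oracle)."""
        f = _textured(seed=2)
        g = np.roll(np.roll(f, -3, axis=0), 7, axis=1)
        reg = register_stack(_stack([f, g]))
        assert reg.shifts[1, 0] == pytest.approx(7, abs=0.5)
        assert reg.shifts[1, 1] == pytest.approx(-3, abs=0.5)

    def test_random_walk_shifts_accumulate(self):
        """20 frames displaced by a random walk (per-step σ = 2 px):
        accumulated estimates within 1 px of ground truth each."""
        rng = np.random.default_rng(8)
        base = _textured((192, 192), seed=5)
        truth = np.cumsum(rng.normal(0, 2, (20, 2)), axis=0)
        truth[0] = 0
        truth = np.round(truth)
        frames = [
            np.roll(np.roll(base, int(t[1]), axis=0), int(t[0]), axis=1)
            for t in truth
        ]
        reg = register_stack(_stack(frames))
        err = np.abs(reg.shifts - truth)
        assert err.max() <= 1.0, f"max accumulated error {err.max():.2f} px"

    def test_featureless_frame_zero_shift_low_confidence(self):
        f = _textured(seed=1)
        flat = np.full_like(f, 99.0)
        reg = register_stack(_stack([f, flat]))
        np.testing.assert_allclose(reg.shifts[1], 0)
        assert reg.confidence[1] == 0.0

    def test_needs_two_frames(self):
        with pytest.raises(ValueError, match="two frames"):
            register_stack(_stack([_textured()]))


def _plan(sections=3, mags=("20x", "100x", "4kx")):
    entries = [
        PlanEntry("r", s, m, 10.0 * s, 5.0 * s, 0.0)
        for m in mags
        for s in range(sections)
    ]
    return NavigationPlan(entries=entries)


def _reg(shifts, sections=None):
    from atnav.refinement import RegistrationResult

    shifts = np.asarray(shifts, float)
    n = len(shifts)
    return RegistrationResult(
        shifts=shifts, rotations=np.zeros(n), confidence=np.ones(n),
        roi_id="r", mag="20x", sections=list(sections or range(n)),
    )


class TestRefinePlan:
    def test_zero_shifts_noop(self):
        plan = _plan()
        out = refine_plan(plan, _reg(np.zeros((3, 2))), 1 / 2.96, "100x")
        assert out.to_dict() == plan.to_dict()

    def test_worked_example_magnitude(self):
        """A correction with components (17.01, 9.47) μm has magnitude
        sqrt(17.01^2 + 9.47^2) ≈ 19.47 μm — under the 20 μm ceiling."""
        px = 1 / 2.96
        shifts = np.array([[0, 0], [17.01 / px, 9.47 / px]])
        rows = corrections_table(_reg(shifts), px)
        sec, dx, dy, mag = rows[1]
        assert dx == pytest.approx(17.01, abs=1e-6)
        assert dy == pytest.approx(9.47, abs=1e-6)
        assert mag == pytest.approx(19.47, abs=0.01)
        assert mag <= 20.0

    def test_only_higher_rungs_updated(self):
        plan = _plan()
        shifts = np.array([[0, 0], [3, -2], [1, 4]], float)
        out = refine_plan(plan, _reg(shifts), 1.0, "100x")
        for e_old, e_new in zip(plan.entries, out.entries):
            if e_old.mag == "20x":
                assert (e_new.x_um, e_new.y_um) == (e_old.x_um, e_old.y_um)
            else:
                k = e_old.section
                assert e_new.x_um == pytest.approx(e_old.x_um + shifts[k, 0])
                assert e_new.y_um == pytest.approx(e_old.y_um + shifts[k, 1])

    def test_corrections_additive(self):
        plan = _plan()
        s1 = np.array([[0, 0], [2, 1], [1, -1]], float)
        s2 = np.array([[0, 0], [-1, 2], [3, 0]], float)
        once = refine_plan(plan, _reg(s1 + s2), 0.5, "100x")
        twice = refine_plan(refine_plan(plan, _reg(s1), 0.5, "100x"),
                            _reg(s2), 0.5, "100x")
        for a, b in zip(once.entries, twice.entries):
            assert a.x_um == pytest.approx(b.x_um, abs=1e-9)
            assert a.y_um == pytest.approx(b.y_um, abs=1e-9)

    def test_mismatched_sections_raise(self):
        plan = _plan(sections=4)
        with pytest.raises(CorrespondenceError):
            refine_plan(plan, _reg(np.zeros((2, 2))), 1.0, "100x")

    def test_refinement_ladder_reduces_median_error(self):
        """End-to-end on a drifting 20-section ribbon with a perfect stage:
        the median ROI navigation error never increases from one refinement
        rung to the next (registration precision grows with magnification)."""
        from atnav.detection import detect_all_sections
        from atnav.focusmap import FocusMap
        from atnav.geometry import Point2D, SectionQuad
        from atnav.imageproc import preprocess_overview
        from atnav.navigation import ROI, acquire_stack, build_plan, calibrate_stage
        from atnav.synthetic import (
            SceneParams,
            SimulatedMicroscope,
            generate_scene,
            render_overview,
        )

        ppm = 2.96
        scene = generate_scene(
            SceneParams(n_ribbons=1, total_sections=20, sections_per_ribbon=(20,),
                        roi_drift_um_per_section=0.5),
            seed=13,
        )
        ov = render_overview(scene, ppm)
        em = preprocess_overview(ov)
        det = detect_all_sections(em, [SectionQuad(scene.ribbons_um[0][0] * ppm)])
        assert det.n_sections == 20
        cal = calibrate_stage(Point2D(0, 0), 1 / ppm)
        traj = scene.rois[0].trajectory_um
        roi = ROI("r", 0, 0, Point2D(*(traj[0] * ppm)))
        w, h = scene.bounds_um()
        fm = FocusMap([[x, y, float(scene.focus_z(x, y))]
                       for x in (0, w) for y in (0, h)])
        plan = build_plan([roi], det, cal, fm, magnifications=["20x", "100x", "4kx"])
        scope = SimulatedMicroscope(scene, jitter_um=0.0, seed=3)

        def med_err(p, mag):
            es = p.for_roi_mag("r", mag)
            return float(np.median([np.hypot(e.x_um - t[0], e.y_um - t[1])
                                    for e, t in zip(es, traj)]))

        errors = [med_err(plan, "20x")]
        st20 = acquire_stack(plan, scope, magnifications=["20x"])[("r", "20x")]
        plan = refine_plan(plan, register_stack(st20), st20.pixel_size, "100x")
        errors.append(med_err(plan, "100x"))
        st100 = acquire_stack(plan, scope, magnifications=["100x"])[("r", "100x")]
        plan = refine_plan(plan, register_stack(st100), st100.pixel_size, "4kx")
        errors.append(med_err(plan, "4kx"))
        # non-increasing in the median, up to the sub-pixel floor set by the
        # ROI's drift relative to its own section's texture (0.1 μm)
        assert all(b <= a + 0.1 for a, b in zip(errors, errors[1:])), errors
        assert errors[-1] <= 0.2 * errors[0], errors
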