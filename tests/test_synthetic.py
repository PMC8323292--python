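"""Ground-truth scene generator, renderer, degradations and the simulated
microscope."""

import numpy as np
import pytest

from atnav.config import MAG_PIXELS_PER_UM
from atnav.synthetic import (
    COVERSLIP_UM,
    LayoutError,
    SceneParams,
    SimulatedMicroscope,
    SyntheticScene,
    degrade_image,
    generate_scene,
    render_overview,
    render_region,
    render_tiles,
)

PPM = 2.96


class TestGenerateScene:
    def test_deterministic_for_params_and_seed(self):
        a = generate_scene(SceneParams(n_ribbons=2, total_sections=34), seed=9)
        b = generate_scene(SceneParams(n_ribbons=2, total_sections=34), seed=9)
        for ra, rb in zip(a.ribbons_um, b.ribbons_um):
            for ca, cb in zip(ra, rb):
                np.testing.assert_array_equal(ca, cb)
        np.testing.assert_array_equal(a.rois[0].trajectory_um, b.rois[0].trajectory_um)

    def test_default_layout_counts(self, full_scene):
        """Proof-of-concept twin: 6 ribbons totalling 126 sections, each
        ribbon holding between 15 and 27."""
        counts = [len(r) for r in full_scene.ribbons_um]
        assert len(counts) == 6
        assert sum(counts) == 126
        assert all(15 <= c <= 27 for c in counts)

    def test_no_drift_limit_gives_congruent_sections(self):
        p = SceneParams(
            n_ribbons=1, total_sections=5, sections_per_ribbon=(5,),
            shrink_per_section=0.0, shear_per_section=0.0,
            curvature_deg_per_section=0.0, corner_jitter_um=0.0,
            ribbon_rotation_deg=0.0,
        )
        scene = generate_scene(p, seed=0)
        first = scene.ribbons_um[0][0]
        for c in scene.ribbons_um[0][1:]:
            rel = c - c.mean(axis=0)
            np.testing.assert_allclose(rel, first - first.mean(axis=0), atol=1e-9)

    def test_roi_drift_bounded(self, full_scene):
        p = full_scene.params
        for roi in full_scene.rois:
            steps = np.diff(roi.trajectory_um, axis=0)
            # trajectory = transfinite address + bounded extra drift; section
            # pitch dominates the step, the drift bound caps the deviation
            # from the address-predicted path
            assert len(roi.trajectory_um) == len(full_scene.ribbons_um[roi.ribbon])
            assert np.all(np.isfinite(steps))

    def test_fits_coverslip(self, full_scene):
        w, h = full_scene.bounds_um()
        assert w < COVERSLIP_UM and h < COVERSLIP_UM

    def test_overlapping_layout_rejected(self):
        p = SceneParams(n_ribbons=2, total_sections=30, ribbon_spacing_um=50.0)
        with pytest.raises(LayoutError):
            generate_scene(p, seed=0)

    def test_json_round_trip(self, small_scene, tmp_path):
        path = tmp_path / "scene.json"
        small_scene.to_json(str(path))
        back = SyntheticScene.from_json(str(path))
        np.testing.assert_allclose(back.ribbons_um[0][3], small_scene.ribbons_um[0][3])
        np.testing.assert_allclose(back.rois[0].trajectory_um, small_scene.rois[0].trajectory_um)
        # textures re-derive from the seed: identical renders
        a = render_region(small_scene, 40, 40, (64, 64), PPM)
        b = render_region(back, 40, 40, (64, 64), PPM)
        np.testing.assert_array_equal(a, b)


class TestRendering:
    def test_corner_projection_consistency(self, small_scene, small_overview):
        """Stage corners in μm land at corner/pixel_size in the raster: dark
        boundary pixels must be found within 0.5 px of each projection."""
        img = small_overview.pixels
        for corners in small_scene.ribbons_um[0]:
            px = corners * PPM
            for x, y in px:
                i, j = int(round(y)), int(round(x))
                patch = img[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
                assert patch.min() < 120, f"no boundary ink near corner ({x:.1f}, {y:.1f})"

    def test_render_is_8bit(self, small_overview):
        assert small_overview.pixels.dtype == np.uint8
        assert small_overview.bit_depth == 8

    def test_tiled_restitch_matches_monolithic(self, small_scene):
        from atnav.imageproc import grid_stitch

        full = render_overview(small_scene, PPM).pixels
        grid, offsets = render_tiles(small_scene, PPM, tile_shape=(256, 256), jitter_px=0.0)
        mosaic = grid_stitch(grid).pixels
        h = min(mosaic.shape[0], full.shape[0])
        w = min(mosaic.shape[1], full.shape[1])
        diff = np.abs(mosaic[:h, :w].astype(float) - full[:h, :w].astype(float))
        assert diff.mean() < 1.0

    def test_window_render_matches_overview_crop(self, small_scene, small_overview):
        """The same scene window rendered standalone equals the overview crop
        (single rendering path)."""
        y0, x0 = 64, 32
        crop = small_overview.pixels[y0:y0 + 96, x0:x0 + 96]
        win = render_region(small_scene, x0 / PPM, y0 / PPM, (96, 96), PPM)
        # identical except for the optics-blur boundary band of the window
        assert np.abs(win.astype(int) - crop.astype(int)).max() <= 1


class TestDegradations:
    def test_zero_noise_is_identity(self, small_overview):
        out = degrade_image(small_overview.pixels, "gaussian", sigma=0.0, seed=1)
        np.testing.assert_array_equal(out, small_overview.pixels)

    def test_gaussian_moment(self):
        """Sample std of the perturbation matches sigma on a mid-gray image
        (far from clipping)."""
        img = np.full((400, 400), 128, np.uint8)
        out = degrade_image(img, "gaussian", sigma=40.0, seed=3)
        sd = (out.astype(float) - 128.0).std()
        assert abs(sd - 40.0) / 40.0 < 0.05

    def test_salt_pepper_fraction(self):
        img = np.full((500, 500), 128, np.uint8)
        out = degrade_image(img, "salt_pepper", fraction=0.02, seed=3)
        flipped = np.mean((out == 0) | (out == 255))
        assert abs(flipped - 0.02) < 0.005

    def test_erase_corners_paints_background(self, small_scene, small_overview):
        polys = [c * PPM for c in small_scene.ribbons_um[0]]
        out = degrade_image(
            small_overview.pixels, "erase_corners", k=4,
            truth_polys_px=polys, seed=0,
        )
        for poly in polys:
            for x, y in poly:
                i, j = int(round(y)), int(round(x))
                patch = out[max(i - 2, 0):i + 3, max(j - 2, 0):j + 3].astype(float)
                assert abs(patch.mean() - 228) < 12, "corner neighbourhood not erased"

    def test_unknown_model_rejected(self, small_overview):
        with pytest.raises(ValueError, match="unknown degradation"):
            degrade_image(small_overview.pixels, "speckle")

    def test_requires_8bit(self):
        with pytest.raises(ValueError, match="8-bit"):
            degrade_image(np.zeros((64, 64), np.uint16), "gaussian")


class TestSimulatedMicroscope:
    def test_deterministic_without_jitter(self, small_scene):
        scope = SimulatedMicroscope(small_scene, jitter_um=0.0, seed=0)
        c = small_scene.ribbons_um[0][2].mean(axis=0)
        scope.move_to(*c)
        scope.set_focus(float(small_scene.focus_z(*c)))
        a = scope.acquire("100x")
        scope.move_to(*c)
        b = scope.acquire("100x")
        np.testing.assert_array_equal(a, b)

    def test_declared_pixel_sizes(self):
        assert MAG_PIXELS_PER_UM["100x"] == pytest.approx(15.38)
        assert MAG_PIXELS_PER_UM["20x"] == pytest.approx(2.96)

    def test_roi_structure_centred_when_on_trajectory(self, small_scene):
        """Acquiring exactly at a ground-truth trajectory point puts the dark
        structure's centre within ~2 px of the frame centre."""
        scope = SimulatedMicroscope(small_scene, jitter_um=0.0, seed=0)
        roi = small_scene.rois[0]
        pos = roi.trajectory_um[3]
        scope.move_to(*pos)
        scope.set_focus(float(small_scene.focus_z(*pos)))
        frame = scope.acquire("100x").astype(float)
        dark = frame < 80
        assert dark.any()
        iy, ix = np.nonzero(dark)
        cy, cx = (np.array(frame.shape) - 1) / 2
        # lobes are recentred at generation, so the dark mass centres on the
        # commanded position up to union-overlap asymmetry
        assert abs(iy.mean() - cy) < 2 * 15.38
        assert abs(ix.mean() - cx) < 2 * 15.38

    def test_out_of_bounds_rejected(self, small_scene):
        scope = SimulatedMicroscope(small_scene)
        with pytest.raises(ValueError, match="out of scene bounds"):
            scope.move_to(-5000.0, 0.0)

    def test_defocus_blurs(self, small_scene):
        scope = SimulatedMicroscope(small_scene, jitter_um=0.0, seed=0)
        c = small_scene.ribbons_um[0][2].mean(axis=0)
        scope.move_to(*c)
        scope.set_focus(float(small_scene.focus_z(*c)))
        sharp = scope.acquire("100x").astype(float)
        scope.set_focus(float(small_scene.focus_z(*c)) + 10.0)
        blurred = scope.acquire("100x").astype(float)
        assert np.abs(np.diff(blurred, axis=1)).mean() < np.abs(np.diff(sharp, axis=1)).mean()
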