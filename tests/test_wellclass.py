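"""Chip layout projection, SAT/FL/NFL classification, sensitivity surfaces."""

import dataclasses
import random

import numpy as np
import pytest

from phantomforge.color import srgb_to_lab, delta_e_2000, roi_mean_color
from phantomforge.synthetic_data import SceneConfig, render_chip_image, render_depth_series
from phantomforge.wellclass import (
    ChipLayout,
    ClassifierConfig,
    Registration,
    build_mask,
    classify_image,
    classify_well,
    estimate_registration_center,
    sensitivity_surface,
)

CFG = ClassifierConfig()


class TestChipLayout:
    def test_default_layout_shape(self):
        layout = ChipLayout()
        assert len(layout.rings) == 5
        assert layout.wells_per_ring == 10
        assert layout.control_index == 9
        assert sorted(d for d, _ in layout.rings) == [100, 250, 500, 1000, 5000]

    def test_overlapping_wells_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ChipLayout(rings=((5000.0, 5000.0),))

    def test_exactly_one_control_required(self):
        with pytest.raises(ValueError, match="control"):
            ChipLayout(concentrations=(450, 300, 180, 120, 80, 55, 40, 25, 16, 8))


class TestBuildMask:
    def test_rois_center_on_rendered_wells(self, bright_scene):
        image, wells = render_chip_image(bright_scene)
        red_excess = image[..., 0] - bright_scene.background_color[0]
        for w in wells:
            if w.concentration == 0 or w.ring_diameter_um < 1000:
                continue
            r0, c0 = int(w.roi.center_row), int(w.roi.center_col)
            # window just covering this well's disc (ROI radius is 0.8x the
            # projected well radius), without touching neighboring wells
            win = int(w.roi.radius / 0.8) + 4
            rlo, clo = max(r0 - win, 0), max(c0 - win, 0)
            patch = red_excess[rlo : r0 + win + 1, clo : c0 + win + 1]
            mask = patch > 0.5 * patch.max()
            rows, cols = np.nonzero(mask)
            cr = rows.mean() + rlo
            cc = cols.mean() + clo
            assert abs(cr - w.roi.center_row) < 1.0
            assert abs(cc - w.roi.center_col) < 1.0

    def test_rotation_by_one_step_relabels_angular_indices(self, small_layout):
        shape = (600, 600)
        reg = Registration(300, 300, 50.0)
        reg_rot = dataclasses.replace(reg, rotation_deg=-36.0)
        base = {(w.ring_diameter_um, w.angular_index): w.roi for w in build_mask(small_layout, shape, reg)}
        rot = {(w.ring_diameter_um, w.angular_index): w.roi for w in build_mask(small_layout, shape, reg_rot)}
        for (d, j), roi in rot.items():
            ref = base[(d, (j + 1) % small_layout.wells_per_ring)]
            assert roi.center_row == pytest.approx(ref.center_row, abs=1e-9)
            assert roi.center_col == pytest.approx(ref.center_col, abs=1e-9)

    def test_offimage_wells_raise_listing_offenders(self, small_layout):
        with pytest.raises(ValueError, match="5000"):
            build_mask(small_layout, (200, 200), Registration(100, 100, 50.0))

    def test_mask_reuse_is_geometry_identical(self, small_layout):
        shape = (600, 600)
        reg = Registration(300, 300, 50.0)
        assert build_mask(small_layout, shape, reg) == build_mask(small_layout, shape, reg)


def _controls(wells):
    return {w.ring_diameter_um: w for w in wells if w.is_control}


class TestClassifyWell:
    def test_channel_saturated_well_is_sat(self, small_layout):
        cfg = SceneConfig(layout=small_layout, gain=1.0, emission_color=(1, 1, 1), seed=0)
        image, wells = render_chip_image(cfg)
        ctl = _controls(wells)
        target = next(w for w in wells if w.concentration == 450 and w.ring_diameter_um == 5000)
        call = classify_well(image, target, ctl[5000], CFG)
        assert call.call == "SAT"
        assert call.delta_e_vs_control is None
        assert call.y_well >= CFG.y_sat

    def test_control_against_itself_is_nfl(self, bright_scene):
        image, wells = render_chip_image(bright_scene)
        ctl = _controls(wells)[5000]
        call = classify_well(image, ctl, ctl, CFG)
        assert call.call == "NFL"
        assert call.delta_e_vs_control == 0.0

    def test_fluorescent_call_delta_e_matches_color_module(self, bright_scene):
        image, wells = render_chip_image(bright_scene)
        ctl = _controls(wells)[5000]
        target = next(w for w in wells if w.concentration == 450 and w.ring_diameter_um == 5000)
        call = classify_well(image, target, ctl, CFG)
        direct = delta_e_2000(
            srgb_to_lab(roi_mean_color(image, target.roi)),
            srgb_to_lab(roi_mean_color(image, ctl.roi)),
        )
        assert call.call == "FL"
        assert call.delta_e_vs_control == pytest.approx(direct, rel=1e-12)

    def test_ring_size_mismatch_rejected(self, bright_scene):
        image, wells = render_chip_image(bright_scene)
        target = next(w for w in wells if w.ring_diameter_um == 5000 and not w.is_control)
        with pytest.raises(ValueError, match="ring size"):
            classify_well(image, target, _controls(wells)[1000], CFG)
        with pytest.raises(ValueError, match="not a control"):
            classify_well(image, target, target, CFG)


class TestClassifyImage:
    def test_dark_chip_is_all_nfl(self, small_layout):
        cfg = SceneConfig(layout=small_layout, gain=0.0, seed=0)
        image, wells = render_chip_image(cfg)
        calls = classify_image(image, wells, CFG)
        assert all(c.call == "NFL" for c in calls)

    def test_repeat_call_is_deterministic(self, bright_scene):
        image, wells = render_chip_image(bright_scene)
        assert classify_image(image, wells, CFG) == classify_image(image, wells, CFG)

    def test_invariant_to_well_evaluation_order(self, bright_scene):
        image, wells = render_chip_image(bright_scene)
        shuffled = list(wells)
        random.Random(3).shuffle(shuffled)
        by_key = lambda calls: {
            (c.well.ring_diameter_um, c.well.angular_index): c.call for c in calls
        }
        assert by_key(classify_image(image, wells, CFG)) == by_key(
            classify_image(image, shuffled, CFG)
        )

    def test_missing_control_rejected(self, bright_scene):
        image, wells = render_chip_image(bright_scene)
        without_controls = [w for w in wells if not w.is_control]
        with pytest.raises(ValueError, match="control"):
            classify_image(image, without_controls, CFG)


class TestSensitivitySurface:
    def test_depth_series_detection_monotone_in_concentration(self, small_layout):
        cfg = SceneConfig(layout=small_layout, gain=5.0e-3, noise_sigma=0.0, seed=2)
        depths = [0.0, 200.0, 400.0, 600.0, 800.0, 1000.0]
        series = render_depth_series(cfg, depths)
        surface = sensitivity_surface(series, small_layout, CFG, cfg.registration())
        md = surface.max_detectable_depth()
        for diameter, grp in md.groupby("ring_diameter_um"):
            grp = grp.sort_values("concentration")
            depths_found = grp["max_detectable_depth"].fillna(-1.0).to_numpy()
            assert np.all(np.diff(depths_found) >= 0), f"ring {diameter}"

    def test_zero_depth_detects_down_to_smallest_concentration(self, bright_scene, small_layout):
        image, _ = render_chip_image(bright_scene)
        surface = sensitivity_surface(
            [(0.0, image)], small_layout, CFG, bright_scene.registration()
        )
        mins = surface.min_detectable_concentration()
        assert (mins["min_detectable_concentration"] == 16.0).all()

    def test_single_image_degenerates_to_classify_image(self, bright_scene, small_layout):
        image, wells = render_chip_image(bright_scene)
        surface = sensitivity_surface(
            [(0.0, image)], small_layout, CFG, bright_scene.registration()
        )
        direct = classify_image(image, wells, CFG)
        assert list(surface.calls["call"]) == [c.call for c in direct]

    def test_duplicate_depths_rejected(self, bright_scene, small_layout):
        image, _ = render_chip_image(bright_scene)
        with pytest.raises(ValueError, match="increasing"):
            sensitivity_surface(
                [(0.0, image), (0.0, image)], small_layout, CFG, bright_scene.registration()
            )

    def test_summary_reports_thresholds(self, bright_scene, small_layout):
        image, _ = render_chip_image(bright_scene)
        surface = sensitivity_surface(
            [(0.0, image)], small_layout, CFG, bright_scene.registration()
        )
        summary = surface.to_summary()
        assert summary["thresholds"] == {"y_sat": 0.98, "delta_e_fl": 3.0}
        assert summary["n_wells"] == 50


class TestRegistrationEstimate:
    def test_center_recovered_on_rendered_chip(self, small_layout):
        cfg = SceneConfig(layout=small_layout, gain=5.0e-3, noise_sigma=0.02, seed=4)
        image, _ = render_chip_image(cfg)
        true = cfg.registration()
        reg, rms = estimate_registration_center(image, small_layout, cfg.um_per_px)
        assert abs(reg.center_row - true.center_row) < 2.0
        assert abs(reg.center_col - true.center_col) < 2.0
        assert rms < 2.0

    def test_dark_image_rejected(self, small_layout):
        image = np.zeros((600, 600, 3))
        with pytest.raises(ValueError, match="outer-ring"):
            estimate_registration_center(image, small_layout, 50.0)
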