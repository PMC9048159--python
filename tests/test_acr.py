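"""ACR-style image-quality metrics on synthetic phantoms with known truth."""

import numpy as np
import pytest

from petmr_qa import acr
from petmr_qa.core import QAError
from petmr_qa.qastats import ToleranceRule, apply_tolerance
from petmr_qa.phantoms import ACRSeriesSpec, gen_acr_like, gen_acr_phantom


class TestSliceThickness:
    def test_recovers_truth_on_default_phantom(self, acr_default):
        vol, truth, cfg = acr_default
        m = acr.measure_slice_thickness(vol, cfg, "T1")
        assert m.value == pytest.approx(truth["slice_thickness_mm"], abs=0.1)
        # symmetric ramps: both FWHM lengths are 10x the thickness
        assert m.meta["L_top_mm"] == pytest.approx(50.0, abs=0.2)
        assert m.meta["L_bottom_mm"] == pytest.approx(50.0, abs=0.2)

    def test_harmonic_mean_formula_with_asymmetric_ramps(self):
        # L_top = 60, L_bot = 42.857: 0.2 * (60 * 42.857)/(102.857) = 5.0
        vol, _ = gen_acr_phantom(ACRSeriesSpec(ramp_asymmetry_mm=10.0))
        m = acr.measure_slice_thickness(vol, acr.ACRGeometryConfig.default())
        assert m.meta["L_top_mm"] == pytest.approx(60.0, abs=0.2)
        assert m.meta["L_bottom_mm"] == pytest.approx(42.857, abs=0.2)
        assert m.value == pytest.approx(5.0, abs=0.1)

    def test_invariant_under_inplane_rotation_with_the_phantom(self):
        vol, _ = gen_acr_phantom(ACRSeriesSpec(inplane_rotation_deg=7.0))
        cfg = acr.ACRGeometryConfig.default().rotated(7.0)
        m = acr.measure_slice_thickness(vol, cfg)
        assert m.value == pytest.approx(5.0, abs=0.1)

    def test_flat_profile_fails_with_ramp_named(self, acr_default):
        vol, _, cfg = acr_default
        from dataclasses import replace

        bad = replace(cfg, ramp_top=acr.LineRegion((0.0, 30.0, 0.0), 20.0, 2.0, 0.0))
        with pytest.raises(QAError, match="top ramp"):
            acr.measure_slice_thickness(vol, bad)


class TestSlicePosition:
    def test_equal_bars_give_zero(self, acr_default):
        vol, _, cfg = acr_default
        assert acr.measure_slice_position(vol, cfg).value == pytest.approx(0.0, abs=0.05)

    def test_recovers_true_offset(self):
        vol, _ = gen_acr_phantom(ACRSeriesSpec(slice_position_offset_mm=2.0))
        m = acr.measure_slice_position(vol, acr.ACRGeometryConfig.default())
        assert m.value == pytest.approx(2.0, abs=0.2)

    def test_bar_length_difference_halved(self):
        # a 2.6 mm bar-length difference reports a 1.3 mm offset
        vol, _ = gen_acr_phantom(ACRSeriesSpec(slice_position_offset_mm=1.3))
        m = acr.measure_slice_position(vol, acr.ACRGeometryConfig.default())
        assert m.meta["L_left_mm"] - m.meta["L_right_mm"] == pytest.approx(2.6, abs=0.1)
        assert m.value == pytest.approx(1.3, abs=0.05)


class TestUniformityAndGhosting:
    def test_uniform_compartment_gives_100(self, acr_default):
        vol, _, cfg = acr_default
        assert acr.measure_uniformity(vol, cfg).value == pytest.approx(100.0, abs=1e-6)

    def test_piu_hand_oracle_dark_patch(self, acr_default):
        vol, _, cfg = acr_default
        vox = vol.voxels.copy()
        k = 3  # uniform-compartment slice
        # 16 mm square patch at 80% signal inside the ROI: high=1000, low=800
        sl = vox[:, :, k]
        i0 = 240 - 16
        sl[i0: i0 + 32, i0: i0 + 32] *= 0.8
        from dataclasses import replace

        vol2 = replace(vol, voxels=vox)
        piu = acr.measure_uniformity(vol2, cfg).value
        assert piu == pytest.approx(100.0 * (1.0 - 200.0 / 1800.0), abs=0.5)

    def test_scaling_invariance(self, acr_default):
        vol, _, cfg = acr_default
        from dataclasses import replace

        scaled = replace(vol, voxels=vol.voxels * 3.7)
        assert acr.measure_uniformity(scaled, cfg).value == pytest.approx(
            acr.measure_uniformity(vol, cfg).value
        )
        assert acr.measure_ghosting(scaled, cfg).value == pytest.approx(
            acr.measure_ghosting(vol, cfg).value
        )

    def test_no_ghost_gives_zero(self, acr_default):
        vol, _, cfg = acr_default
        assert acr.measure_ghosting(vol, cfg).value == pytest.approx(0.0, abs=1e-9)

    def test_injected_ghost_fraction_recovered(self):
        vol, truth = gen_acr_phantom(ACRSeriesSpec(ghost_fraction=0.02))
        m = acr.measure_ghosting(vol, acr.ACRGeometryConfig.default())
        assert m.value == pytest.approx(truth["ghosting_pct"], abs=0.05)

    def test_ghosting_hand_oracle(self, acr_default):
        # top=bottom=+4, left=right=+1 on a phantom of mean 1000:
        # 100 * |8 - 2| / 2000 = 0.3 %
        vol, _, cfg = acr_default
        vox = vol.voxels.copy()
        sl = vox[:, :, 3]
        for name, add in (("top", 4.0), ("bottom", 4.0), ("left", 1.0), ("right", 1.0)):
            mask = acr._ellipse_mask(vol, sl, cfg.ghost_rois[name], 0.0)
            sl[mask] += add
        from dataclasses import replace

        m = acr.measure_ghosting(replace(vol, voxels=vox), cfg)
        assert m.value == pytest.approx(0.3, abs=1e-6)

    def test_ghost_roi_overlapping_phantom_fails(self, acr_default):
        vol, _, cfg = acr_default
        from dataclasses import replace

        bad = replace(cfg, ghost_rois={**cfg.ghost_rois, "top": acr.EllipseROI((0.0, -60.0, 5.0), (20.0, 8.0))})
        with pytest.raises(QAError, match="overlaps the phantom"):
            acr.measure_ghosting(vol, bad)


class TestResolution:
    def test_sharp_phantom_resolves_smallest_array(self, acr_default):
        vol, _, cfg = acr_default
        m = acr.assess_resolution(vol, cfg)
        assert m.value == 0.9

    def test_blur_removes_smallest_array(self):
        vol, _ = gen_acr_phantom(ACRSeriesSpec(psf_sigma_mm=0.45))
        m = acr.assess_resolution(vol, acr.ACRGeometryConfig.default())
        assert m.value == 1.0
        assert m.meta["resolved"] == {"1.1": True, "1.0": True, "0.9": False}

    def test_nothing_resolved_warns_and_returns_largest(self):
        vol, _ = gen_acr_phantom(ACRSeriesSpec(psf_sigma_mm=1.2))
        m = acr.assess_resolution(vol, acr.ACRGeometryConfig.default())
        assert m.value == 1.1
        assert m.meta["warnings"]


class TestLowContrast:
    def test_score_stored_verbatim_and_compared_to_tolerance(self):
        m = acr.record_low_contrast(35, "T1", observer="AB")
        assert m.value == 35.0
        assert m.meta["observer"] == "AB"
        verdict = apply_tolerance(m, ToleranceRule("ge", limit=37.0))
        assert verdict["verdict"] == "fail"

    def test_boundary_passes_inclusively(self):
        m = acr.record_low_contrast(37, "T2", observer="AB")
        assert apply_tolerance(m, ToleranceRule("ge", limit=37.0))["verdict"] == "pass"

    def test_out_of_range_rejected(self):
        with pytest.raises(QAError):
            acr.record_low_contrast(41, "T1", "AB")
        with pytest.raises(QAError):
            acr.record_low_contrast(-1, "T1", "AB")


def test_analyse_series_and_t1_t2_generation():
    (t1, truth1), (t2, truth2) = gen_acr_like()
    cfg = acr.ACRGeometryConfig.default()
    r1 = acr.analyse_series(t1, cfg, "T1", low_contrast=38, observer="AB")
    r2 = acr.analyse_series(t2, cfg, "T2")
    for r, truth in ((r1, truth1), (r2, truth2)):
        assert r.slice_thickness == pytest.approx(truth["slice_thickness_mm"], abs=0.1)
        assert r.piu == pytest.approx(100.0, abs=1e-6)
        assert r.ghosting == pytest.approx(0.0, abs=1e-9)
    assert r1.low_contrast == 38
    assert r2.low_contrast is None
    assert len(r1.to_measurements("s1")) == 6
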