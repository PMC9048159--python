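"""Vial segmentation, two-point ADC estimation and reference interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petmr_qa.adc import (
    SUBSTANCES,
    ReferenceADCTable,
    adc_report,
    compute_adc,
    default_reference_table,
    fit_adc_multib,
    reference_adc,
    segment_vials,
)
from petmr_qa.core import QAError
from petmr_qa.phantoms import DWVialSpec, dw_vial_masks, gen_dw_vials


class TestSegmentation:
    def test_three_masks_close_to_true_voxel_counts(self):
        from scipy import ndimage

        spec = DWVialSpec(snr_b50=50.0, seed=11)
        vols = gen_dw_vials(spec)
        masks = segment_vials(vols[0])
        assert len(masks) == 3
        for m, t in zip(masks, dw_vial_masks(spec)):
            eroded_truth = ndimage.binary_erosion(t)
            assert abs(int(m.sum()) - int(eroded_truth.sum())) <= 0.05 * eroded_truth.sum()

    def test_masks_are_disjoint_and_ordered_by_x(self):
        spec = DWVialSpec(seed=1)
        masks = segment_vials(gen_dw_vials(spec)[0])
        assert not (masks[0] & masks[1]).any()
        assert not (masks[1] & masks[2]).any()
        from scipy import ndimage

        xs = [ndimage.center_of_mass(m)[0] for m in masks]
        assert xs == sorted(xs)

    def test_missing_vial_is_failure(self):
        spec = DWVialSpec(seed=1)
        vols = gen_dw_vials(spec)
        truth = dw_vial_masks(spec)
        vols[0].voxels[truth[2]] = 0.0  # drain one vial
        with pytest.raises(QAError, match="expected 3 vials"):
            segment_vials(vols[0])


class TestADCEstimator:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        adc=st.floats(0.5e-3, 2.5e-3),
        b_low=st.floats(0.0, 400.0),
        delta=st.floats(50.0, 1500.0),
    )
    def test_exact_on_noiseless_mono_exponential(self, adc, b_low, delta):
        spec = DWVialSpec(vial_true_adc=(adc, adc, adc), b_values=(b_low, b_low + delta))
        vols = gen_dw_vials(spec)
        out = compute_adc(vols[0], vols[1], dw_vial_masks(spec))
        for r in out:
            assert r["adc"] == pytest.approx(adc, abs=1e-12)

    def test_equal_signals_give_zero(self):
        from dataclasses import replace

        spec = DWVialSpec(vial_true_adc=(1e-3,) * 3)
        vols = gen_dw_vials(spec)
        same = replace(vols[0], meta={"b_value": 800.0})
        out = compute_adc(vols[0], same, dw_vial_masks(spec))
        assert all(r["adc"] == 0.0 for r in out)

    def test_full_pipeline_bias_below_2pct_at_snr_50(self):
        # Monte-Carlo over 10 seeds: segmentation + two-point estimate
        errs = {s: [] for s in range(3)}
        for seed in range(10):
            spec = DWVialSpec(snr_b50=50.0, seed=100 + seed)
            vols = gen_dw_vials(spec)
            masks = segment_vials(vols[0])
            out = compute_adc(vols[0], vols[1], masks)
            for v, (r, truth) in enumerate(zip(out, spec.vial_true_adc)):
                errs[v].append(abs(r["adc"] - truth) / truth)
        for v in errs:
            assert np.mean(errs[v]) < 0.02

    def test_rician_bias_decreases_with_snr(self):
        # estimator bias (truth masks, no segmentation noise) at four SNRs
        biases = []
        for snr in (10.0, 25.0, 50.0, 100.0):
            rel = []
            for seed in range(25):
                spec = DWVialSpec(
                    vial_true_adc=(1.2e-3,) * 3, snr_b50=snr, voxel_mm=3.0, seed=1000 + seed
                )
                vols = gen_dw_vials(spec)
                out = compute_adc(vols[0], vols[1], dw_vial_masks(spec))
                rel.extend(abs(r["adc"] - 1.2e-3) / 1.2e-3 for r in out)
            biases.append(np.mean(rel))
        assert biases == sorted(biases, reverse=True)

    def test_mismatched_grids_rejected(self):
        spec = DWVialSpec()
        a, b = gen_dw_vials(spec)
        from dataclasses import replace

        with pytest.raises(QAError, match="share a grid"):
            compute_adc(a, replace(b, origin=(1.0, 0.0, 0.0)), dw_vial_masks(spec))

    def test_multib_fit_matches_truth_noiseless(self):
        spec = DWVialSpec(b_values=(50.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 1250.0, 1500.0))
        vols = gen_dw_vials(spec)
        out = fit_adc_multib(vols, dw_vial_masks(spec))
        for r, truth in zip(out, spec.vial_true_adc):
            assert r["adc"] == pytest.approx(truth, rel=1e-9)


class TestReferenceTable:
    def test_tabulated_node_returned_exactly(self):
        table = ReferenceADCTable({"nonane": ([20.0, 22.0], [2.0e-3, 2.2e-3])})
        assert reference_adc(table, "nonane", 22.0) == 2.2e-3

    def test_linear_midpoint(self):
        table = ReferenceADCTable({"nonane": ([20.0, 22.0], [2.0e-3, 2.2e-3])})
        assert reference_adc(table, "nonane", 21.0) == pytest.approx(2.1e-3)

    def test_extrapolation_refused_unless_flagged(self):
        table = ReferenceADCTable({"nonane": ([20.0, 22.0], [2.0e-3, 2.2e-3])})
        with pytest.raises(QAError, match="outside reference range"):
            reference_adc(table, "nonane", 25.0)
        assert reference_adc(table, "nonane", 25.0, extrapolate=True) == pytest.approx(2.5e-3)

    def test_shipped_default_table_is_valid(self):
        table = default_reference_table()
        assert set(SUBSTANCES) <= set(table.entries)
        for sub in SUBSTANCES:
            assert reference_adc(table, sub, 21.0) > 0

    def test_non_monotone_temperatures_rejected(self):
        with pytest.raises(QAError):
            ReferenceADCTable({"nonane": ([22.0, 20.0], [2.0e-3, 2.2e-3])})


class TestADCReport:
    TABLE = ReferenceADCTable({s: ([15.0, 30.0], [1.0e-3, 1.0e-3]) for s in SUBSTANCES})

    def test_measured_equals_reference_gives_zero(self):
        res = adc_report([{"adc": 1.0e-3}] * 3, SUBSTANCES, self.TABLE, 21.0, 21.0)
        assert [v["percent_difference"] for v in res.per_vial] == pytest.approx([0.0] * 3)

    def test_two_percent_high_measurement(self):
        res = adc_report([{"adc": 1.02e-3}] * 3, SUBSTANCES, self.TABLE, 21.0, 21.0)
        assert res.per_vial[0]["percent_difference"] == pytest.approx(2.0)

    def test_reference_evaluated_at_mean_temperature(self):
        table = ReferenceADCTable({s: ([20.0, 22.0], [2.0e-3, 2.2e-3]) for s in SUBSTANCES})
        res = adc_report([{"adc": 2.12e-3}] * 3, SUBSTANCES, table, 21.0, 21.4)
        assert res.temp_mean == pytest.approx(21.2)
        assert res.per_vial[0]["reference_adc"] == pytest.approx(2.12e-3)

    def test_unequilibrated_phantom_warns(self):
        res = adc_report([{"adc": 1.0e-3}] * 3, SUBSTANCES, self.TABLE, 19.0, 21.0)
        assert res.warnings

    def test_percent_difference_first_order_antisymmetry(self):
        # pd(m, r) = -pd(r, m) * (m / r), exactly
        def pd(m, r):
            return 100.0 * (m - r) / r

        m, r = 1.07e-3, 0.93e-3
        assert pd(m, r) == pytest.approx(-pd(r, m) * (m / r), abs=1e-12)
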