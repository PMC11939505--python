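"""Endpoint math: Cavalieri volume, mineralized fraction, relative density,
segmentation, socket evaluation and group summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socketry.metrics import (
    DensityUndefinedError,
    SliceMeasurement,
    ThresholdRule,
    evaluate_socket,
    mineralized_fraction,
    relative_density,
    segment_mineralized,
    socket_volume,
    summarize,
    summarize_group,
)
from socketry.roi import PolygonRoi
from socketry.volume_io import StudyRecord


class TestSocketVolume:
    def test_closed_form(self):
        assert socket_volume([4.0, 4.0, 4.0], 0.4) == pytest.approx(4.8)
        assert socket_volume([10.0], 0.5) == pytest.approx(5.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            socket_volume([], 0.4)
        with pytest.raises(ValueError):
            socket_volume([1.0, -0.1], 0.4)
        with pytest.raises(ValueError):
            socket_volume([1.0], 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        areas=st.lists(st.floats(0, 1e3), min_size=1, max_size=30),
        thickness=st.floats(1e-3, 10),
        k=st.floats(1e-3, 1e3),
    )
    def test_linear_in_areas_and_thickness(self, areas, thickness, k):
        v = socket_volume(areas, thickness)
        assert socket_volume([a * k for a in areas], thickness) == pytest.approx(k * v)
        assert socket_volume(areas, thickness * k) == pytest.approx(k * v)


class TestMineralizedFraction:
    @pytest.mark.parametrize("vmin,valv,expected", [(30, 40, 75.0), (0, 40, 0.0), (40, 40, 100.0)])
    def test_closed_form(self, vmin, valv, expected):
        assert mineralized_fraction(vmin, valv) == pytest.approx(expected)

    def test_invariant_to_uniform_area_rescale(self):
        areas_alv, areas_min, t = [3.0, 4.0, 5.0], [1.0, 2.0, 3.0], 0.4
        f = mineralized_fraction(socket_volume(areas_min, t), socket_volume(areas_alv, t))
        f2 = mineralized_fraction(
            socket_volume([a * 7 for a in areas_min], t),
            socket_volume([a * 7 for a in areas_alv], t),
        )
        assert f2 == pytest.approx(f)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            mineralized_fraction(1.0, 0.0)


class TestRelativeDensity:
    def test_closed_form_and_anchors(self):
        # q1 = 0.2, q2 = 0.6 -> 100 * 0.4 / 0.8
        assert relative_density(20, 100, 60, 100) == pytest.approx(50.0)
        assert relative_density(20, 100, 20, 100) == pytest.approx(0.0)  # no change
        assert relative_density(20, 100, 100, 100) == pytest.approx(100.0)  # reference bone

    def test_gain_invariance_exact(self):
        base = relative_density(30, 120, 70, 110)
        assert relative_density(30, 120, 70 * 1.3, 110 * 1.3) == pytest.approx(base)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a1=st.floats(5, 60), r1=st.floats(90, 200), r2=st.floats(90, 200),
        a2=st.floats(5, 190), gain=st.floats(0.5, 2.0),
    )
    def test_gain_invariance_property(self, a1, r1, r2, a2, gain):
        assert relative_density(a1, r1, a2 * gain, r2 * gain) == pytest.approx(
            relative_density(a1, r1, a2, r2)
        )

    def test_strictly_increasing_in_t2_gray(self):
        vals = [relative_density(30, 120, a2, 110) for a2 in (40, 60, 90, 110)]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_baseline_floor(self):
        with pytest.raises(DensityUndefinedError, match="baseline"):
            relative_density(98, 100, 99, 100)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            relative_density(20, 0, 60, 100)


class TestSegmentMineralized:
    def _half_bright(self):
        img = np.full((20, 20), 20, np.uint8)
        img[:, 10:] = 200
        return img

    def test_half_bright_fixed_threshold(self):
        img = self._half_bright()
        roi = PolygonRoi(0, [(2, 2), (18, 2), (18, 18), (2, 18)])
        seg = segment_mineralized(
            img, roi, ThresholdRule("fixed_gray", 100), pixel_area_mm2=0.04
        )
        assert seg.mineralized_area_mm2 == pytest.approx(0.04 * 16 * 8)  # right half of ROI
        assert seg.mineralized_mean_gray == pytest.approx(200.0)

    def test_fraction_of_reference_threshold_value(self):
        img = self._half_bright()
        roi = PolygonRoi(0, [(2, 2), (18, 2), (18, 18), (2, 18)])
        seg = segment_mineralized(
            img, roi, ThresholdRule("fraction_of_reference", 0.5),
            pixel_area_mm2=0.04, reference_mean_gray=180.0,
        )
        assert seg.threshold == pytest.approx(90.0)

    def test_threshold_above_slice_max_gives_zero_area(self):
        img = self._half_bright()
        roi = PolygonRoi(0, [(2, 2), (18, 2), (18, 18), (2, 18)])
        seg = segment_mineralized(img, roi, ThresholdRule("fixed_gray", 250), pixel_area_mm2=0.04)
        assert seg.mineralized_area_mm2 == 0.0
        assert math.isnan(seg.mineralized_mean_gray)

    def test_otsu_recovers_known_fill_fraction(self, rng):
        # bimodal ROI: 70 % bright at 150, 30 % dark at 40, sigma 5
        img = rng.normal(40, 5, (30, 40))
        img[:21, :] = rng.normal(150, 5, (21, 40))
        img = np.clip(img, 0, 255).astype(np.uint8)
        roi = PolygonRoi(0, [(0, 0), (40, 0), (40, 30), (0, 30)])
        seg = segment_mineralized(img, roi, ThresholdRule("otsu_within_roi"), pixel_area_mm2=1.0)
        assert seg.mineralized_area_mm2 / (30 * 40) == pytest.approx(0.7, abs=0.05)


def slice_m(idx, tp, area=4.0, gray=40.0, ref=140.0, min_area=None, min_gray=None):
    return SliceMeasurement(
        slice_index=idx, alveolar_area_mm2=area, alveolar_mean_gray=gray,
        reference_mean_gray=ref, timepoint=tp,
        mineralized_area_mm2=min_area, mineralized_mean_gray=min_gray,
    )


class TestEvaluateSocket:
    def test_no_regeneration_gives_zero_endpoints(self):
        t1 = [slice_m(i, "t1") for i in range(5)]
        t2 = [slice_m(i, "t2", min_area=0.0) for i in range(5)]
        res = evaluate_socket(t1, t2, 0.4)
        assert res.mineralized_percent == 0.0
        assert res.density_percent == 0.0
        assert "no_detectable_mineralization" in res.quality_flags

    def test_full_fill_at_reference_gray_saturates(self):
        t1 = [slice_m(i, "t1") for i in range(5)]
        t2 = [slice_m(i, "t2", gray=140.0, min_area=4.0, min_gray=140.0) for i in range(5)]
        res = evaluate_socket(t1, t2, 0.4)
        assert res.mineralized_percent == pytest.approx(100.0)
        assert res.density_percent == pytest.approx(100.0)

    def test_volumes_use_common_slices_and_flag_unmatched(self):
        t1 = [slice_m(i, "t1") for i in range(6)]
        t2 = [slice_m(i, "t2", min_area=2.0, min_gray=90.0) for i in range(5)]
        res = evaluate_socket(t1, t2, 0.4)
        assert res.n_slices == 5
        assert res.V_alv_mm3 == pytest.approx(5 * 4.0 * 0.4)
        assert any(f.startswith("unmatched_slices") for f in res.quality_flags)

    def test_disjoint_slices_error(self):
        with pytest.raises(ValueError, match="common"):
            evaluate_socket([slice_m(0, "t1")], [slice_m(5, "t2", min_area=1.0)], 0.4)

    def test_area_weighted_density_grays(self):
        # two slices with different mineralized areas: new-bone gray must
        # be pooled by area, not averaged per slice
        t1 = [slice_m(0, "t1"), slice_m(1, "t1")]
        t2 = [
            slice_m(0, "t2", min_area=3.0, min_gray=90.0),
            slice_m(1, "t2", min_area=1.0, min_gray=130.0),
        ]
        res = evaluate_socket(t1, t2, 0.4)
        pooled = (3 * 90 + 1 * 130) / 4.0
        expected = relative_density(40.0, 140.0, pooled, 140.0)
        assert res.density_percent == pytest.approx(expected)


class TestSummaries:
    def test_mean_and_sample_sd(self):
        out = summarize([70.0, 80.0])
        assert out["n"] == 2
        assert out["mean"] == pytest.approx(75.0)
        assert out["sd"] == pytest.approx(7.0710678, rel=1e-6)

    def test_single_value_sd_undefined(self):
        out = summarize([70.0])
        assert out["n"] == 1 and out["sd"] is None

    def test_empty_stratum_reported_as_zero(self):
        assert summarize([]) == {"n": 0, "mean": None, "sd": None}

    def test_stratified_counts_on_synthetic_cohort(self):
        from socketry.metrics import SocketResult

        def result(pct):
            return SocketResult(
                V_alv_mm3=100, V_min_mm3=pct, mineralized_percent=pct,
                density_percent=pct / 2, slice_thickness_mm=0.4, n_slices=10,
            )

        records = []
        for i in range(19):  # 19 molars split 7 type-1 / 12 type-2
            rec = StudyRecord(
                socket_id=f"m{i}", tooth_class="molar",
                socket_type="1" if i < 7 else "2",
            )
            records.append((rec, result(60.0 + i)))
        df = summarize_group(records)
        at = df.set_index(["socket_type", "tooth_class"])
        assert at.loc[("all", "molar"), "mineralized_percent_n"] == 19
        assert at.loc[("1", "molar"), "mineralized_percent_n"] == 7
        assert at.loc[("2", "molar"), "mineralized_percent_n"] == 12
        assert at.loc[("all", "premolar"), "mineralized_percent_n"] == 0
        assert at.loc[("all", "premolar"), "mineralized_percent_mean"] is None or np.isnan(
            at.loc[("all", "premolar"), "mineralized_percent_mean"]
        )
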