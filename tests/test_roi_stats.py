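import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octhrombus import optics, roi_stats
from octhrombus.errors import AnalysisError
from octhrombus.oct_io import PolarFrame, RegionMask
from octhrombus.optics import AttenuationMap, BackscatterMap
from octhrombus.roi_stats import (
    RegionStatistics,
    apply_attenuation_threshold,
    patient_summary,
    region_statistics,
    select_reference_fragment,
)


def make_att(mu_values, valid=None, shape=None):
    mu = np.asarray(mu_values, dtype=float)
    if shape is not None:
        mu = mu.reshape(shape)
    if valid is None:
        valid = np.ones_like(mu, dtype=bool)
    return AttenuationMap(mu=mu, valid=valid, axial_pitch_mm=0.005, catheter_offset=0,
                          noise_floor=0.0, processed=np.maximum(mu, 0.0))


def make_mask(member):
    return RegionMask.from_array(np.asarray(member))


class TestApplyThreshold:
    def test_enumerated_example_015(self):
        att = make_att([[0.1, 0.2, 0.6, 0.8]])
        mask = make_mask([[1, 1, 1, 1]])
        result = apply_attenuation_threshold(mask, att, 0.15)
        assert result.included_pixels == 3
        assert result.excluded_fraction == pytest.approx(0.25)

    def test_all_above_threshold_unchanged(self):
        att = make_att([[0.2, 0.6, 0.8]])
        mask = make_mask([[1, 1, 1]])
        result = apply_attenuation_threshold(mask, att, 0.15)
        np.testing.assert_array_equal(result.member, mask.member)
        assert result.excluded_fraction == 0.0

    def test_enumerated_example_05(self):
        att = make_att([[0.1, 0.2, 0.6, 0.8]])
        mask = make_mask([[1, 1, 1, 1]])
        result = apply_attenuation_threshold(mask, att, 0.5)
        assert result.included_pixels == 2
        assert result.excluded_fraction == pytest.approx(0.5)

    def test_empty_mask_fraction_missing(self):
        att = make_att([[0.1, 0.2]])
        result = apply_attenuation_threshold(make_mask([[0, 0]]), att, 0.15)
        assert result.included_pixels == 0
        assert result.excluded_fraction is None

    def test_invalid_pixels_excluded(self):
        valid = np.array([[True, False, True]])
        att = make_att([[0.9, 0.9, 0.9]], valid=valid)
        result = apply_attenuation_threshold(make_mask([[1, 1, 1]]), att, 0.15)
        assert result.included_pixels == 2

    def test_negative_threshold_rejected(self):
        att = make_att([[0.1]])
        with pytest.raises(AnalysisError):
            apply_attenuation_threshold(make_mask([[1]]), att, -0.1)

    @settings(max_examples=50, deadline=None)
    @given(
        mu=st.lists(st.floats(0, 3, allow_nan=False), min_size=1, max_size=50),
        thresholds=st.tuples(st.floats(0, 3), st.floats(0, 3)),
    )
    def test_excluded_fraction_monotone_in_threshold(self, mu, thresholds):
        att = make_att([mu])
        mask = make_mask([[1] * len(mu)])
        lo, hi = sorted(thresholds)
        f_lo = apply_attenuation_threshold(mask, att, lo).excluded_fraction
        f_hi = apply_attenuation_threshold(mask, att, hi).excluded_fraction
        assert f_lo <= f_hi


def reference_statistics(values):
    """Direct-formula oracle for the nine statistics."""
    values = sorted(values)
    n = len(values)
    mean = sum(values) / n
    out = {"mean": mean, "median": float(np.median(values))}
    out["sd"] = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    out["skewness"] = m3 / m2**1.5
    out["kurtosis"] = m4 / m2**2 - 3.0
    for p, name in [(5, "p5"), (10, "p10"), (90, "p90"), (95, "p95")]:
        # linear interpolation between order statistics
        h = (n - 1) * p / 100.0
        lo = math.floor(h)
        out[name] = values[lo] + (h - lo) * (values[min(lo + 1, n - 1)] - values[lo])
    return out


def stats_from_values(att_values, gray_values=None):
    """Build a 1-row region and compute its statistics."""
    att_values = np.asarray(att_values, dtype=float)
    gray = att_values if gray_values is None else np.asarray(gray_values, dtype=float)
    frame = PolarFrame(gray.reshape(1, -1), 0.005, 0)
    att = make_att(att_values.reshape(1, -1))
    b = BackscatterMap(b=att.mu.copy(), valid=np.ones_like(att.mu, dtype=bool), gain=0.0)
    filt = apply_attenuation_threshold(make_mask([[1] * att_values.size]), att, 0.0)
    return region_statistics(frame, att, b, filt)


class TestRegionStatistics:
    def test_constant_region(self):
        stats = stats_from_values([7.0] * 5)
        for name in ("mean", "median", "p5", "p10", "p90", "p95"):
            assert stats.value("grayscale", name) == 7.0
        assert stats.value("grayscale", "sd") == 0.0
        assert math.isnan(stats.value("grayscale", "skewness"))
        assert math.isnan(stats.value("grayscale", "kurtosis"))

    def test_outlier_sample_matches_oracle(self):
        values = [1.0, 2.0, 3.0, 4.0, 100.0]
        stats = stats_from_values(values)
        oracle = reference_statistics(values)
        assert stats.value("attenuation", "mean") == pytest.approx(22.0)
        assert stats.value("attenuation", "median") == pytest.approx(3.0)
        for name, expected in oracle.items():
            assert stats.value("attenuation", name) == pytest.approx(expected, rel=1e-12), name

    def test_symmetric_values_zero_skewness(self):
        values = np.arange(-5.0, 6.0) + 10.0
        stats = stats_from_values(values)
        assert abs(stats.value("attenuation", "skewness")) < 1e-12

    def test_single_pixel_higher_moments_missing(self):
        stats = stats_from_values([4.2])
        assert stats.value("grayscale", "mean") == 4.2
        assert math.isnan(stats.value("grayscale", "sd"))
        assert math.isnan(stats.value("grayscale", "skewness"))

    def test_no_pixels_raises(self):
        att = make_att([[0.1]])
        filt = apply_attenuation_threshold(make_mask([[1]]), att, 2.0)
        frame = PolarFrame(np.ones((1, 1)), 0.005, 0)
        b = BackscatterMap(b=att.mu, valid=att.valid, gain=0.0)
        with pytest.raises(AnalysisError):
            region_statistics(frame, att, b, filt)

    def test_percentile_ordering_invariant(self, rng):
        stats = stats_from_values(rng.exponential(1.0, 200))
        s = stats.channels["attenuation"]
        assert s["p5"] <= s["p10"] <= s["median"] <= s["p90"] <= s["p95"]


class TestSelectReferenceFragment:
    def make(self, arr, mu):
        mask = make_mask(arr)
        att = make_att(mu)
        return mask, att

    def test_largest_fragment_wins(self):
        arr = np.zeros((10, 20), dtype=int)
        arr[0:4, 0:5] = 1  # 20 px -> label 1
        arr[6:9, 10:14] = 1  # 12 px -> label 2
        mask, att = self.make(arr, np.full((10, 20), 0.5))
        assert select_reference_fragment(mask, att) == 1

    def test_tie_broken_by_mean_attenuation(self):
        arr = np.zeros((4, 8), dtype=int)
        arr[0:2, 0:2] = 1
        arr[0:2, 5:7] = 1  # equal 4-px fragments
        mu = np.zeros((4, 8))
        mu[0:2, 0:2] = 0.5
        mu[0:2, 5:7] = 0.9
        mask, att = self.make(arr, mu)
        labels = mask.fragment_labels
        expected = int(labels[0, 5])
        assert select_reference_fragment(mask, att) == expected

    def test_single_fragment(self):
        arr = np.zeros((4, 4), dtype=int)
        arr[1:3, 1:3] = 1
        mask, att = self.make(arr, np.ones((4, 4)))
        assert select_reference_fragment(mask, att) == 1

    def test_empty_mask_raises(self):
        mask, att = self.make(np.zeros((2, 2), dtype=int), np.ones((2, 2)))
        with pytest.raises(AnalysisError):
            select_reference_fragment(mask, att)


def make_region_stats(median_att=1.0, included=100, patient_id="P1", frame_id="f0",
                      channels=None, **overrides):
    base = {s: 1.0 for s in roi_stats.STATISTICS}
    chans = {}
    for c in roi_stats.CHANNELS:
        chans[c] = dict(base)
    chans["attenuation"]["median"] = median_att
    if channels:
        for c, d in channels.items():
            chans[c].update(d)
    return RegionStatistics(
        channels=chans, included_pixels=included, excluded_pixels=0,
        threshold_mm=0.15, frame_id=frame_id, patient_id=patient_id, **overrides
    )


class TestPatientSummary:
    def test_weighted_median_example(self):
        s1 = make_region_stats(median_att=1.0, included=100, frame_id="f0")
        s2 = make_region_stats(median_att=2.0, included=300, frame_id="f1")
        summary = patient_summary([s1, s2])
        assert summary.value("attenuation", "median") == pytest.approx(1.75)
        assert summary.total_pixels == 400

    def test_equal_counts_plain_mean(self):
        s1 = make_region_stats(median_att=1.0, included=50)
        s2 = make_region_stats(median_att=3.0, included=50)
        assert patient_summary([s1, s2]).value("attenuation", "median") == pytest.approx(2.0)

    def test_ratio_example(self):
        s = make_region_stats(
            channels={"attenuation": {"p95": 1.50}, "grayscale": {"median": 68.0}}
        )
        summary = patient_summary([s])
        assert summary.ratio_att95_over_medint == pytest.approx(0.02206, abs=1e-5)

    def test_zero_median_grayscale_ratio_missing(self):
        s = make_region_stats(channels={"grayscale": {"median": 0.0}})
        assert math.isnan(patient_summary([s]).ratio_att95_over_medint)

    def test_single_frame_identity(self):
        s = make_region_stats(median_att=0.77)
        summary = patient_summary([s])
        for c in roi_stats.CHANNELS:
            for name in roi_stats.STATISTICS:
                assert summary.value(c, name) == s.value(c, name)

    def test_mixed_patients_rejected(self):
        s1 = make_region_stats(patient_id="P1")
        s2 = make_region_stats(patient_id="P2")
        with pytest.raises(AnalysisError):
            patient_summary([s1, s2])

    def test_zero_total_pixels_rejected(self):
        s = make_region_stats(included=0)
        with pytest.raises(AnalysisError):
            patient_summary([s])

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.01, 5, allow_nan=False), st.integers(1, 1000)),
            min_size=1, max_size=6,
        )
    )
    def test_aggregate_within_per_frame_bounds(self, data):
        stats = [make_region_stats(median_att=v, included=w, frame_id=f"f{i}")
                 for i, (v, w) in enumerate(data)]
        summary = patient_summary(stats)
        values = [v for v, _ in data]
        agg = summary.value("attenuation", "median")
        assert min(values) - 1e-12 <= agg <= max(values) + 1e-12
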