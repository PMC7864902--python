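"""Trace peak detection, valley segmentation, and area ratios."""

import math

import numpy as np
import pytest

from protract.polysome import (
    FractionSignal,
    Trace,
    _region_area,
    analyze_trace,
    default_labels,
    detect_peaks,
    fraction_in_lane,
    segment_trace,
)
from protract.synthetic import TraceSpec, gen_trace


def gaussian_trace(centres, widths, areas, n=500, span=(0.0, 100.0), baseline=0.0):
    x = np.linspace(*span, n)
    y = np.full_like(x, baseline, dtype=float)
    for c, w, a in zip(centres, widths, areas):
        y += a / (w * math.sqrt(2 * math.pi)) * np.exp(-((x - c) ** 2) / (2 * w**2))
    return Trace(positions=x, absorbance=y)


class TestDetectPeaks:
    def test_single_gaussian_centre(self):
        trace = gaussian_trace([50.0], [3.0], [2.0])
        peaks = detect_peaks(trace)
        assert peaks.size == 1
        true_idx = np.argmin(np.abs(trace.positions - 50.0))
        assert abs(peaks[0] - true_idx) <= 1

    def test_two_separated_gaussians(self):
        trace = gaussian_trace([30.0, 70.0], [3.0, 3.0], [2.0, 1.0])
        assert detect_peaks(trace).size == 2

    def test_four_peak_trace_with_noise(self):
        spec = TraceSpec(
            centres=(25.0, 45.0, 65.0, 85.0),
            widths=(2.0, 2.0, 2.0, 2.0),
            areas=(1.0, 3.0, 2.0, 1.5),
            labels=("40S", "60S", "80S", "polysome_1"),
            noise_sd=0.02,
            seed=7,
        )
        trace, _ = gen_trace(spec)
        peaks = detect_peaks(trace)
        assert peaks.size == 4
        for centre, idx in zip(spec.centres, peaks):
            true_idx = np.argmin(np.abs(trace.positions - centre))
            assert abs(idx - true_idx) <= 2

    def test_flat_trace_rejected(self):
        flat = Trace(np.linspace(0, 10, 60), np.ones(60))
        with pytest.raises(ValueError, match="flat"):
            detect_peaks(flat)

    def test_no_peaks_advises_threshold(self):
        # pure ramp: monotone, no local maxima
        ramp = Trace(np.linspace(0, 10, 60), np.linspace(0, 1, 60))
        with pytest.raises(ValueError, match="min_prominence"):
            detect_peaks(ramp)

    def test_bad_prominence(self):
        trace = gaussian_trace([50.0], [3.0], [1.0])
        with pytest.raises(ValueError):
            detect_peaks(trace, min_prominence=1.5)


class TestSegmentTrace:
    def test_triangle_area_is_analytic(self):
        # isoceles triangle, base 20 height 1, on a flat baseline of 0.1,
        # flanked by a second bump so segmentation has two peaks
        x = np.linspace(0, 100, 1001)
        y = np.full_like(x, 0.1)
        y += np.clip(1 - np.abs(x - 30) / 10, 0, None)
        y += np.clip(0.5 - np.abs(x - 70) / 8, 0, None) * 1.0
        trace = Trace(x, y)
        seg = analyze_trace(trace, labels=["60S", "80S"])
        assert seg.area("60S") == pytest.approx(10.0, rel=0.01)  # 0.5*20*1

    def test_equal_gaussians_give_unit_ratio(self):
        trace = gaussian_trace([35.0, 65.0], [2.0, 2.0], [3.0, 3.0], baseline=0.05)
        seg = analyze_trace(trace, labels=["60S", "80S"])
        assert seg.ratio_60_80 == pytest.approx(1.0, rel=0.05)

    def test_noiseless_pm_recovery_within_2_percent(self):
        spec = TraceSpec(noise_sd=0.0)
        trace, truth = gen_trace(spec)
        seg = analyze_trace(trace)
        assert truth["pm_ratio"] == pytest.approx(2.5)
        assert seg.pm_ratio == pytest.approx(truth["pm_ratio"], rel=0.02)

    def test_region_labels_follow_position_order(self):
        trace, _ = gen_trace(TraceSpec(noise_sd=0.0))
        seg = analyze_trace(trace)
        assert [r.label for r in seg.regions] == [
            "40S", "60S", "80S", "polysome_1", "polysome_2", "polysome_3", "polysome_4",
        ]
        assert all(
            r1.end_index == r2.start_index for r1, r2 in zip(seg.regions, seg.regions[1:])
        )

    def test_fewer_than_two_peaks_rejected(self):
        trace = gaussian_trace([50.0], [3.0], [1.0])
        with pytest.raises(ValueError, match="2 labelled peaks"):
            segment_trace(trace, [250])

    def test_label_override(self):
        trace = gaussian_trace([35.0, 65.0], [2.0, 2.0], [3.0, 1.0])
        seg = analyze_trace(trace, labels=["80S", "polysome_1"])
        assert seg.pm_ratio == pytest.approx(seg.area("polysome_1") / seg.area("80S"))

    def test_missing_labels_give_nan_ratios(self):
        trace = gaussian_trace([35.0, 65.0], [2.0, 2.0], [3.0, 1.0])
        seg = analyze_trace(trace, labels=["40S", "60S"])
        assert math.isnan(seg.pm_ratio)
        assert math.isnan(seg.ratio_60_80)

    def test_default_labels_scheme(self):
        assert default_labels(5) == ["40S", "60S", "80S", "polysome_1", "polysome_2"]


class TestAreaProperties:
    def test_additivity_under_shared_baseline(self):
        trace, _ = gen_trace(TraceSpec(noise_sd=0.0))
        anchors = np.zeros(len(trace))  # shared flat baseline
        lo, hi = 100, 500
        for mid in (200, 333, 400):
            total = _region_area(trace.positions, trace.absorbance, anchors, lo, hi)
            split = _region_area(
                trace.positions, trace.absorbance, anchors, lo, mid
            ) + _region_area(trace.positions, trace.absorbance, anchors, mid, hi)
            assert abs(total - split) < 1e-9

    def test_scale_equivariance(self):
        trace, _ = gen_trace(TraceSpec(noise_sd=0.01, seed=3))
        seg = analyze_trace(trace)
        k = 7.5
        scaled = Trace(trace.positions, k * trace.absorbance)
        seg_k = analyze_trace(scaled)
        for r, rk in zip(seg.regions, seg_k.regions):
            assert rk.area == pytest.approx(k * r.area, rel=1e-9)
        assert seg_k.pm_ratio == pytest.approx(seg.pm_ratio, rel=1e-9)
        assert seg_k.ratio_60_80 == pytest.approx(seg.ratio_60_80, rel=1e-9)

    def test_noisy_recovery_sample(self):
        hits = 0
        for seed in range(10):
            trace, truth = gen_trace(TraceSpec(noise_sd=0.02, seed=seed))
            seg = analyze_trace(trace)
            if (
                abs(seg.pm_ratio / truth["pm_ratio"] - 1) < 0.1
                and abs(seg.ratio_60_80 / truth["ratio_60_80"] - 1) < 0.1
            ):
                hits += 1
        assert hits >= 9


class TestFractionInLane:
    def test_uniform_signal(self):
        sig = FractionSignal(tuple(str(i) for i in range(1, 9)), (1.0,) * 8)
        assert fraction_in_lane(sig, "6") == pytest.approx(0.125)

    def test_concentrated_signal(self):
        sig = FractionSignal(("5", "6"), (0.0, 2.0))
        assert fraction_in_lane(sig, "6") == 1.0

    def test_random_vectors_match_sum_ratio(self, rng):
        for _ in range(20):
            values = rng.uniform(0.1, 5.0, size=8)
            sig = FractionSignal(tuple(str(i) for i in range(8)), tuple(values))
            lane = str(rng.integers(0, 8))
            assert fraction_in_lane(sig, lane) == pytest.approx(
                values[int(lane)] / values.sum()
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            FractionSignal(("1", "2"), (0.0, 0.0))

    def test_unknown_lane(self):
        sig = FractionSignal(("1", "2"), (1.0, 1.0))
        with pytest.raises(KeyError):
            fraction_in_lane(sig, "9")


class TestTraceValidation:
    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            Trace(np.arange(10.0), np.zeros(10))

    def test_non_monotone_positions_rejected(self):
        pos = np.arange(60.0)
        pos[30] = 0.0
        with pytest.raises(ValueError, match="increasing"):
            Trace(pos, np.zeros(60))
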