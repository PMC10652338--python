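import numpy as np
import pytest

from cocmatrix import nanopore
from cocmatrix.nanopore import (
    CalibrationCurve,
    CurrentTrace,
    DetectionParams,
    detect_events,
    estimate_baseline,
    lowpass,
    map_mw,
    summarize_polydispersity,
)
from cocmatrix.synthetic import MwDistributionSpec, TraceSpec, gen_trace

FS = 200_000.0


def flat_trace(value=1000.0, seconds=0.5, noise=0.0, seed=0):
    n = int(FS * seconds)
    x = np.full(n, value)
    if noise > 0:
        x = x + np.random.default_rng(seed).normal(0, noise, n)
    return CurrentTrace(samples=x, sampling_hz=FS)


def inject(x, onset_s, dur_s, depth):
    s = int(onset_s * FS)
    ln = max(1, round(dur_s * FS))
    x[s : s + ln] -= depth


class TestEstimateBaseline:
    def test_constant_noiseless(self):
        b, s = estimate_baseline(flat_trace(1000.0))
        assert b == 1000.0
        assert s == 0.0

    def test_gaussian_noise_sigma_vs_filter_oracle(self):
        # oracle: pass the same white noise through the same filter and
        # measure its sd directly
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 10.0, int(FS))
        filtered = lowpass(CurrentTrace(noise, FS), 5000.0).samples
        oracle_sd = filtered.std()
        trace = lowpass(CurrentTrace(1000.0 + noise, FS), 5000.0)
        _, sigma = estimate_baseline(trace)
        assert sigma == pytest.approx(oracle_sd, rel=0.10)

    def test_robust_to_deep_dips(self):
        trace = flat_trace(1000.0, noise=5.0, seed=2)
        x = trace.samples.copy()
        n = x.size
        # 5% of samples in deep dips
        for k in range(10):
            start = int(n * (0.05 + 0.09 * k))
            x[start : start + n // 200] -= 300.0
        b, _ = estimate_baseline(CurrentTrace(x, FS))
        assert abs(b - 1000.0) < 1.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="10 ms"):
            estimate_baseline(CurrentTrace(np.ones(100), FS))


class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass(flat_trace(7.0, 0.1), 5000.0)
        assert np.allclose(out.samples, 7.0)

    def test_corner_attenuation_near_3db(self):
        t = np.arange(int(FS * 0.5)) / FS
        tr = CurrentTrace(np.sin(2 * np.pi * 5000.0 * t), FS)
        out = lowpass(tr, 5000.0).samples
        mid = out[len(out) // 4 : 3 * len(out) // 4]
        assert mid.max() == pytest.approx(1 / np.sqrt(2), rel=0.10)

    def test_white_noise_variance_contracts(self):
        tr = flat_trace(0.0, 0.5, noise=10.0, seed=3)
        out = lowpass(tr, 5000.0)
        assert out.samples.var() < tr.samples.var()

    def test_corner_at_nyquist_is_noop(self):
        tr = flat_trace(1000.0, 0.05, noise=4.0, seed=4)
        out = lowpass(tr, FS / 2.0)
        assert np.array_equal(out.samples, tr.samples)

    def test_zero_phase_no_onset_shift(self):
        x = np.full(int(FS * 0.2), 500.0)
        inject(x, 0.1, 1e-3, 50.0)
        filtered = lowpass(CurrentTrace(x, FS), 5000.0).samples
        deficit = 500.0 - filtered
        centroid = np.average(np.arange(x.size), weights=np.abs(deficit))
        center = int(0.1 * FS) + round(1e-3 * FS) / 2
        assert abs(centroid - center) <= 3


class TestDetectEvents:
    def test_flat_noiseless_empty(self):
        events = detect_events(
            flat_trace(), DetectionParams(abs_threshold_pa=5.0)
        )
        assert events == []

    def test_zero_noise_without_fallback_errors(self):
        with pytest.raises(ValueError, match="abs_threshold"):
            detect_events(flat_trace())

    def test_ten_events_count_and_duration(self):
        # DERIVED oracle: the EventTruth sidecar (here injected directly)
        rng = np.random.default_rng(0)
        noise = 5.0
        x = np.full(int(FS * 2.0), 2000.0) + rng.normal(0, noise, int(FS * 2.0))
        durs = np.geomspace(100e-6, 1e-3, 10)
        onsets = np.linspace(0.1, 1.8, 10)
        for d, o in zip(durs, onsets):
            inject(x, o, d, 10 * noise)
        events = detect_events(CurrentTrace(x, FS))
        assert len(events) == 10
        for d, ev in zip(durs, events):
            truth = round(d * FS) / FS
            assert abs(ev.duration_s - truth) * FS <= 2.0

    def test_duration_window_filter(self):
        # 10 us: below the analysis bandwidth, attenuated under threshold;
        # 3 ms: beyond the duration window. 30 us and 2 ms retained.
        x = np.full(int(FS * 1.0), 4000.0)
        for dur, onset in [(10e-6, 0.2), (30e-6, 0.4), (2e-3, 0.6), (3e-3, 0.8)]:
            inject(x, onset, dur, 50.0)
        events = detect_events(
            CurrentTrace(x, FS), DetectionParams(abs_threshold_pa=10.0)
        )
        assert len(events) == 2
        assert events[0].onset_s == pytest.approx(0.4, abs=1e-3)
        assert events[1].onset_s == pytest.approx(0.6, abs=1e-3)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        x = np.full(int(FS * 1.0), 2000.0) + rng.normal(0, 5.0, int(FS))
        for o in (0.2, 0.5, 0.8):
            inject(x, o, 500e-6, 60.0)
        ev0 = detect_events(CurrentTrace(x, FS))
        ev1 = detect_events(CurrentTrace(x + 123.4, FS))
        assert len(ev0) == len(ev1) == 3
        for a, b in zip(ev0, ev1):
            assert a.duration_s == pytest.approx(b.duration_s, abs=1e-9)
            assert a.area_pa_s == pytest.approx(b.area_pa_s, rel=1e-6)

    def test_concatenation_union(self):
        def trace_with(seed, onsets):
            rng = np.random.default_rng(seed)
            x = np.full(int(FS * 0.5), 2000.0) + rng.normal(0, 5.0, int(FS * 0.5))
            for o in onsets:
                inject(x, o, 400e-6, 60.0)
            return x

        xa = trace_with(1, (0.15, 0.3))
        xb = trace_with(2, (0.2, 0.4))
        na = len(detect_events(CurrentTrace(xa, FS)))
        nb = len(detect_events(CurrentTrace(xb, FS)))
        nc = len(detect_events(CurrentTrace(np.concatenate([xa, xb]), FS)))
        assert nc == na + nb

    def test_events_sorted_non_overlapping(self):
        rng = np.random.default_rng(9)
        x = np.full(int(FS * 1.0), 2000.0) + rng.normal(0, 5.0, int(FS))
        for o in np.linspace(0.1, 0.9, 8):
            inject(x, o, 300e-6, 70.0)
        events = detect_events(CurrentTrace(x, FS))
        ends = [e.onset_s + e.duration_s for e in events]
        assert all(events[i + 1].onset_s >= ends[i] for i in range(len(events) - 1))

    def test_area_against_truth(self):
        rng = np.random.default_rng(11)
        x = np.full(int(FS * 1.0), 2000.0) + rng.normal(0, 2.0, int(FS))
        depth, dur = 40.0, 800e-6
        inject(x, 0.5, dur, depth)
        (event,) = detect_events(CurrentTrace(x, FS))
        assert event.area_pa_s == pytest.approx(depth * dur, rel=0.05)


class TestCalibrationCurve:
    def test_interpolation_at_node(self, power_law_cal):
        area = power_law_cal.areas_pa_s[3]
        assert power_law_cal.mw_for_area(area) == pytest.approx(
            power_law_cal.mw_kda[3]
        )

    def test_log_log_geometric_midpoint(self):
        cal = CalibrationCurve(areas_pa_s=[1e-3, 4e-3], mw_kda=[100.0, 900.0])
        mid_area = np.sqrt(1e-3 * 4e-3)
        assert cal.mw_for_area(mid_area) == pytest.approx(np.sqrt(100.0 * 900.0))

    def test_inverse_round_trip(self, power_law_cal):
        mw = np.geomspace(60, 5000, 20)
        back = power_law_cal.mw_for_area(power_law_cal.area_for_mw(mw))
        assert np.allclose(back, mw, rtol=1e-9)

    def test_monotonicity_required(self):
        with pytest.raises(ValueError, match="increasing"):
            CalibrationCurve(areas_pa_s=[1e-3, 1e-3], mw_kda=[100.0, 200.0])

    def test_sub_50_kda_start_rejected(self):
        with pytest.raises(ValueError, match="50"):
            CalibrationCurve(areas_pa_s=[1e-4, 1e-3], mw_kda=[10.0, 200.0])

    def test_common_scale_invariance(self, power_law_cal):
        events = [
            nanopore.NanoporeEvent(0.0, 1e-3, 1.0, a)
            for a in (1e-3, 5e-3, 2e-2)
        ]
        scaled_cal = CalibrationCurve(
            areas_pa_s=power_law_cal.areas_pa_s * 7.0, mw_kda=power_law_cal.mw_kda
        )
        scaled_events = [
            nanopore.NanoporeEvent(0.0, 1e-3, 1.0, a * 7.0)
            for a in (1e-3, 5e-3, 2e-2)
        ]
        mw0 = [s.mw_kda for s in map_mw(events, power_law_cal)]
        mw1 = [s.mw_kda for s in map_mw(scaled_events, scaled_cal)]
        assert mw0 == pytest.approx(mw1, rel=1e-9)


class TestMapMw:
    def test_below_range_flagged(self, power_law_cal):
        ev = nanopore.NanoporeEvent(0.0, 1e-3, 1.0, 1e-6)
        (sized,) = map_mw([ev], power_law_cal)
        assert sized.flag == "below-calibration"
        assert not sized.usable

    def test_above_range_excluded_by_default(self, power_law_cal):
        ev = nanopore.NanoporeEvent(0.0, 1e-3, 1.0, 1.0)
        (sized,) = map_mw([ev], power_law_cal)
        assert sized.flag == "above-calibration"

    def test_above_range_clamp_option(self, power_law_cal):
        ev = nanopore.NanoporeEvent(0.0, 1e-3, 1.0, 1.0)
        (sized,) = map_mw([ev], power_law_cal, above_range="clamp")
        assert sized.usable
        assert sized.mw_kda == power_law_cal.mw_kda[-1]

    def test_flagged_excluded_from_summary(self, power_law_cal):
        events = [
            nanopore.NanoporeEvent(0.0, 1e-3, 1.0, 1e-6),  # below
            nanopore.NanoporeEvent(0.1, 1e-3, 1.0, 2e-3),  # in range
        ]
        sized = map_mw(events, power_law_cal)
        usable = [s.mw_kda for s in sized if s.usable]
        result = summarize_polydispersity(usable, min_events=1)
        assert result.n_events == 1


class TestSummarizePolydispersity:
    def test_all_at_cutoff_strict_inequality(self):
        res = summarize_polydispersity([300.0] * 10, min_events=5)
        assert res.weighted_avg_mw_kda == pytest.approx(300.0)
        assert res.fraction_below[300.0] == 0.0

    def test_mass_weighted_hand_arithmetic(self):
        res = summarize_polydispersity([100.0, 100.0, 400.0], min_events=1)
        assert res.number_avg_mw_kda == pytest.approx(200.0)
        assert res.weighted_avg_mw_kda == pytest.approx(300.0)

    def test_qc_threshold(self):
        assert not summarize_polydispersity([100.0] * 499).qc_pass
        assert summarize_polydispersity([100.0] * 500).qc_pass

    def test_histogram_sums_to_one(self, rng):
        mws = rng.uniform(60, 4000, 1000)
        res = summarize_polydispersity(mws)
        assert res.histogram_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weighted_avg_within_range(self, rng):
        mws = rng.uniform(60, 4000, 200)
        res = summarize_polydispersity(mws, min_events=1)
        assert mws.min() <= res.weighted_avg_mw_kda <= mws.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_polydispersity([])


class TestEndToEndRecovery:
    def test_fraction_and_weighted_avg(self, power_law_cal):
        spec = TraceSpec(
            duration_s=4.0, event_rate_hz=40.0, noise_sd_pa=1.0,
            min_depth_pa=8.0, seed=21,
            mw_spec=MwDistributionSpec(),
        )
        trace, truth = gen_trace(spec, power_law_cal)
        assert len(truth) >= 100
        _, res = nanopore.size_trace(trace, power_law_cal, min_events=100)
        true_mw = np.array([t.true_mw_kda for t in truth])
        assert abs(res.fraction_below[300.0] - np.mean(true_mw < 300)) <= 0.05
        true_wavg = np.sum(true_mw**2) / np.sum(true_mw)
        assert res.weighted_avg_mw_kda == pytest.approx(true_wavg, rel=0.10)
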