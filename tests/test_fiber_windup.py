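"""Latency gating, raster construction/smoothing, and wind-up normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nociquant import fiber_windup as fw
from nociquant import synthgen
from nociquant.io_pipeline import SpikeTrain


def naive_smooth(counts, k_trial, k_lat):
    """Double-loop normalized 2-D convolution with zero padding — the oracle."""
    n, m = counts.shape
    ht, hl = len(k_trial) // 2, len(k_lat) // 2
    out = np.zeros_like(counts, dtype=float)
    for i in range(n):
        for j in range(m):
            num = den = 0.0
            for di in range(-ht, ht + 1):
                for dj in range(-hl, hl + 1):
                    ii, jj = i + di, j + dj
                    w = k_trial[di + ht] * k_lat[dj + hl]
                    den += w if 0 <= ii < n and 0 <= jj < m else 0.0
                    if 0 <= ii < n and 0 <= jj < m:
                        num += w * counts[ii, jj]
            out[i, j] = num / den
    return out


class TestClassifySpikeLatency:
    @pytest.mark.parametrize(
        "latency,expected",
        [
            (10.0, "abeta"),
            (20.0, "adelta"),  # half-open boundary belongs to the upper window
            (150.0, "c"),
            (500.0, "post_discharge"),
            (850.0, "none"),
            (-1.0, "none"),
        ],
    )
    def test_window_membership(self, latency, expected):
        assert fw.classify_spike_latency(latency) == expected

    def test_vectorized_matches_scalar(self):
        lats = np.array([0.0, 19.999, 20.0, 89.9, 90.0, 299.9, 300.0, 799.9, 800.0])
        vec = fw.classify_spike_latencies(lats)
        assert list(vec) == [fw.classify_spike_latency(v) for v in lats]

    def test_generated_spikes_gate_into_their_source_class(self):
        # every simulated spike must classify into the window it was drawn from
        cfg = synthgen.WDRSimConfig(seed=42, n_trials=50, gap_after_trial=None)
        train, proto, _ = synthgen.simulate_wdr_recording(cfg)
        raster_trial = np.searchsorted(proto.shock_times_s, train.times_s, side="right") - 1
        latencies = (train.times_s - proto.shock_times_s[raster_trial]) * 1000.0
        assert np.all(fw.classify_spike_latencies(latencies) != "none")

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fw.classify_spike_latency(float("nan"))


class TestBuildRaster:
    def test_no_spikes_zero_matrix(self):
        raster = fw.build_raster(SpikeTrain("u", np.empty(0)), np.arange(5.0))
        assert raster.counts.shape == (5, 800)
        assert raster.counts.sum() == 0

    def test_single_spike_lands_in_trial_and_bin(self):
        train = SpikeTrain("u", np.array([3.1505]))
        raster = fw.build_raster(train, np.arange(10.0), bin_ms=1.0)
        assert raster.counts[3, 150] == 1
        assert raster.counts.sum() == 1

    def test_total_count_equals_direct_count(self):
        rng = np.random.default_rng(0)
        times = np.unique(rng.uniform(0, 30, size=400))
        shocks = np.arange(30.0)
        raster = fw.build_raster(SpikeTrain("u", times), shocks, max_latency_ms=800.0)
        # oracle: count spikes whose latency to the preceding shock is < 800 ms
        direct = sum(
            1
            for t in times
            if t >= shocks[0] and (t - shocks[shocks <= t][-1]) * 1000.0 < 800.0
        )
        assert raster.counts.sum() == direct
        assert raster.counts.sum() + raster.n_unassigned == times.size

    def test_empty_shock_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fw.build_raster(SpikeTrain("u", np.array([1.0])), np.empty(0))

    def test_bin_must_divide_max_latency(self):
        with pytest.raises(ValueError, match="divide"):
            fw.build_raster(SpikeTrain("u", np.empty(0)), np.arange(3.0), bin_ms=3.0,
                            max_latency_ms=800.0)


class TestSmoothRaster:
    def test_interior_impulse_conserves_mass(self):
        counts = np.zeros((60, 300))
        counts[30, 150] = 1.0
        raster = fw.Raster(counts, 1.0, np.arange(60.0), 300.0)
        sm = fw.smooth_raster(raster)
        assert sm.counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_matrix_preserved_exactly(self):
        counts = np.full((40, 100), 3.7)
        raster = fw.Raster(counts, 1.0, np.arange(40.0), 100.0)
        sm = fw.smooth_raster(raster)
        np.testing.assert_allclose(sm.counts, counts, atol=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(20, 20)).astype(float)
        raster = fw.Raster(counts, 1.0, np.arange(20.0), 20.0)
        sm = fw.smooth_raster(raster, h_window_ms=9.0, v_window_ms=7.0, sd=3.0)
        k_lat = fw._truncated_gaussian(9.0, 3.0)
        k_trial = fw._truncated_gaussian(7.0, 3.0)
        np.testing.assert_allclose(sm.counts, naive_smooth(counts, k_trial, k_lat), atol=1e-10)

    def test_invalid_widths_rejected(self):
        raster = fw.Raster(np.zeros((5, 5)), 1.0, np.arange(5.0), 5.0)
        with pytest.raises(ValueError):
            fw.smooth_raster(raster, h_window_ms=-1.0)


class TestCountCWindow:
    def test_window_definition(self):
        # spikes at 100, 400 and 900 ms: only the first two fall in [90, 800)
        train = SpikeTrain("u", np.array([0.100, 0.400, 0.900]))
        raster = fw.build_raster(train, np.array([0.0]), max_latency_ms=1000.0)
        counts = fw.count_c_window(raster, (90.0, 800.0))
        assert counts.tolist() == [2.0]

    def test_zero_raster_zero_vector(self):
        raster = fw.Raster(np.zeros((4, 800)), 1.0, np.arange(4.0), 800.0)
        assert fw.count_c_window(raster).tolist() == [0.0] * 4

    def test_equals_direct_latency_count(self):
        rng = np.random.default_rng(2)
        times = np.unique(rng.uniform(0, 20, size=300))
        shocks = np.arange(20.0)
        raster = fw.build_raster(SpikeTrain("u", times), shocks)
        counts = fw.count_c_window(raster, (90.0, 800.0))
        lat = (times - shocks[np.searchsorted(shocks, times, side="right") - 1]) * 1000.0
        assert counts.sum() == np.sum((lat >= 90.0) & (lat < 800.0))

    def test_window_outside_support_rejected(self):
        raster = fw.Raster(np.zeros((4, 100)), 1.0, np.arange(4.0), 100.0)
        with pytest.raises(ValueError):
            fw.count_c_window(raster, (90.0, 800.0))


class TestNormalizeWindup:
    def test_constant_counts_flat_hundred(self):
        norm = fw.normalize_windup(np.full(50, 6.0))
        np.testing.assert_allclose(norm.percent, 100.0)

    def test_isolated_burst_max_window_contains_burst_trial(self):
        counts = np.zeros(60)
        counts[30] = 10.0
        norm = fw.normalize_windup(counts)
        # all 21-trial windows containing the burst tie at the maximum; the
        # earliest wins, and the winning window must cover the burst trial
        assert norm.max_window[0] <= 30 < norm.max_window[1]
        assert norm.percent[30] == pytest.approx(100.0)

    def test_moving_mean_max_is_exactly_100(self):
        rng = np.random.default_rng(3)
        norm = fw.normalize_windup(rng.poisson(8.0, size=200).astype(float))
        assert norm.percent.max() == 100.0

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, factor):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5.0, size=100).astype(float) + 1.0
        a = fw.normalize_windup(counts)
        b = fw.normalize_windup(counts * factor)
        np.testing.assert_allclose(a.percent, b.percent, rtol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fw.normalize_windup(np.zeros(30))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fw.normalize_windup(np.ones(10), window_trials=21)


class TestPercentReduction:
    def test_flat_trace_zero_reduction(self):
        norm = fw.normalize_windup(np.full(300, 5.0))
        assert fw.percent_reduction(norm, (140.0, 180.0), 40.0) == pytest.approx(0.0)

    def test_arithmetic(self):
        # a trace whose window minimum is 38.7 % gives a 61.3 % reduction
        counts = np.full(300, 10.0)
        counts[200:230] = 3.87
        norm = fw.normalize_windup(counts)
        red = fw.percent_reduction(norm, (140.0, 180.0), 40.0)
        assert red == pytest.approx(100.0 - norm.percent[180:220].min())
        assert norm.percent[180:220].min() < 50.0

    def test_trials_in_gaps_are_absent_not_zero(self):
        counts = np.full(100, 8.0)
        times = np.concatenate([np.arange(50.0), 300.0 + np.arange(50.0)])
        norm = fw.normalize_windup(counts, times)
        with pytest.raises(ValueError, match="window"):
            fw.percent_reduction(norm, (100.0, 150.0), 0.0)  # inside the gap

    def test_empty_window_rejected(self):
        norm = fw.normalize_windup(np.full(50, 5.0))
        with pytest.raises(ValueError):
            fw.percent_reduction(norm, (140.0, 180.0), 40.0)

    def test_generator_suppression_recovered(self):
        cfg = synthgen.WDRSimConfig(seed=5)
        train, proto, _ = synthgen.simulate_wdr_recording(cfg)
        bundle = fw.windup_analysis(train, proto.shock_times_s, t0_s=40.0)
        assert bundle.result.reductions["140-180"] == pytest.approx(61.0, abs=12.0)


class TestWULatencyMetrics:
    def test_max_latency_reported_relative_to_t0(self):
        # unimodal bump peaking at trial 35: the moving-mean max sits there too
        counts = 100.0 - np.abs(np.arange(100.0) - 35.0)
        norm = fw.normalize_windup(counts)
        lat_max, _, _ = fw.wu_latency_metrics(norm, 0.0)
        assert lat_max == pytest.approx(35.0)

    def test_v_shape_half_crossing_midway(self):
        counts = np.concatenate([np.linspace(10, 1, 50), np.linspace(1, 10, 50)])
        norm = fw.normalize_windup(counts)
        lat_max, lat_min, lat_half = fw.wu_latency_metrics(norm, 0.0)
        assert lat_max < lat_half < lat_min
        half_level = (norm.percent.max() + norm.percent.min()) / 2.0
        idx = int(lat_half)
        assert norm.percent[idx] <= half_level <= norm.percent[idx - 1]

    def test_monotone_trace_missing_values(self):
        counts = np.linspace(1, 20, 60)
        norm = fw.normalize_windup(counts)
        lat_max, lat_min, lat_half = fw.wu_latency_metrics(norm, 0.0)
        assert lat_max == pytest.approx(59.0)
        assert np.isnan(lat_min) and np.isnan(lat_half)

    def test_suppression_trough_located_within_smoothing_window(self):
        # a sharp suppression (fast decay) puts an identifiable trough in the trace
        cfg = synthgen.WDRSimConfig(seed=6, suppression_decay_s=200.0)
        train, proto, truth = synthgen.simulate_wdr_recording(cfg)
        bundle = fw.windup_analysis(train, proto.shock_times_s, t0_s=40.0)
        per = truth.per_trial
        # post-plateau trough: the expected-intensity minimum after light onset
        first = per[(per["time_s"] >= 40.0) & (per["time_s"] < 290.0)]
        truth_trough = float(
            first["time_s"].iloc[int(np.argmin(first["lambda_c"].to_numpy()))] - 40.0
        )
        assert abs(bundle.result.latency_to_min_s - truth_trough) <= 21.0 + 5.0
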