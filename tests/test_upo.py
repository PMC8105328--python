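import numpy as np
import pytest

from nystlab.upo import (
    IntervalSequence,
    crossing_intervals,
    locate_upo_segment,
    surrogate_significance,
    transform_intervals,
    upo_histogram,
    upo_from_trace,
)

from .conftest import make_trace


def sign_scan_oracle(x, rate, threshold=0.0):
    """Brute-force rising sign-change scan with linear interpolation."""
    times = []
    for i in range(1, len(x)):
        if x[i - 1] < threshold <= x[i]:
            frac = (threshold - x[i - 1]) / (x[i] - x[i - 1])
            times.append((i - 1 + frac) / rate)
    return np.diff(times)


class TestCrossingIntervals:
    def test_sine_intervals_equal_period(self):
        rate = 200.0
        t = np.arange(int(20 * rate)) / rate
        tr = make_trace(2.0 * np.sin(2 * np.pi * 0.5 * t), rate=rate)
        seq = crossing_intervals(tr, threshold=0.0, direction="rising")
        np.testing.assert_allclose(seq.intervals, 2.0, atol=1 / rate)

    def test_falling_direction(self):
        rate = 200.0
        t = np.arange(int(20 * rate)) / rate
        tr = make_trace(np.sin(2 * np.pi * 0.5 * t), rate=rate)
        seq = crossing_intervals(tr, direction="falling")
        np.testing.assert_allclose(seq.intervals, 2.0, atol=1 / rate)

    def test_constant_trace_errors(self):
        with pytest.raises(ValueError):
            crossing_intervals(make_trace(np.zeros(1000)))

    def test_too_few_crossings_errors(self):
        rate = 200.0
        t = np.arange(int(2 * rate)) / rate  # one cycle: 1 rising crossing
        tr = make_trace(np.sin(2 * np.pi * 0.5 * t), rate=rate)
        with pytest.raises(ValueError, match="fewer than 3"):
            crossing_intervals(tr)

    def test_noisy_sine_matches_sign_scan_oracle(self, rng):
        rate = 200.0
        t = np.arange(int(30 * rate)) / rate
        x = np.sin(2 * np.pi * 1.0 * t) + 0.05 * rng.standard_normal(t.size)
        tr = make_trace(x, rate=rate)
        seq = crossing_intervals(tr, hysteresis=0.0)
        np.testing.assert_allclose(seq.intervals, sign_scan_oracle(x, rate), atol=1e-12)

    def test_hysteresis_suppresses_chatter(self, rng):
        rate = 200.0
        t = np.arange(int(30 * rate)) / rate
        x = np.sin(2 * np.pi * 0.5 * t) + 0.1 * rng.standard_normal(t.size)
        tr = make_trace(x, rate=rate)
        raw = crossing_intervals(tr, hysteresis=0.0)
        clean = crossing_intervals(tr, hysteresis=0.4)
        assert len(clean) < len(raw)
        assert np.median(clean.intervals) == pytest.approx(2.0, abs=0.1)


class TestTransformIntervals:
    def test_identical_intervals_use_fallback(self):
        seq = IntervalSequence(np.full(10, 2.0), 0.0, "rising", sample_period=0.005)
        tp = transform_intervals(seq)
        np.testing.assert_allclose(tp.estimates, 2.0)
        assert tp.excluded_count == 8

    def test_affine_contraction_recovers_fixed_point(self):
        # I_{n+1} = 0.5 I_n + 1 from I_1 = 4 -> fixed point 1 / (1 - 0.5) = 2
        I = [4.0]
        for _ in range(9):
            I.append(0.5 * I[-1] + 1.0)
        tp = transform_intervals(np.asarray(I), denom_tol=1e-12)
        np.testing.assert_allclose(tp.estimates, 2.0, atol=1e-9)
        assert tp.excluded_count == 0

    def test_matches_per_triple_oracle(self, rng):
        I = 2.0 + 0.3 * rng.standard_normal(50)
        I = np.abs(I) + 0.1
        tp = transform_intervals(I, denom_tol=1e-9)
        expected = []
        for n in range(1, len(I) - 1):
            k = (I[n + 1] - I[n]) / (I[n] - I[n - 1])
            if abs(I[n] - I[n - 1]) < 1e-9 or abs(1 - k) < 1e-6:
                expected.append(I[n])
            else:
                expected.append((I[n + 1] - k * I[n]) / (1 - k))
        np.testing.assert_allclose(tp.estimates, expected, rtol=1e-12)

    def test_too_few_intervals_errors(self):
        with pytest.raises(ValueError):
            transform_intervals(np.array([1.0, 2.0]))

    def test_estimate_count_bound(self, rng):
        I = np.abs(rng.normal(2.0, 0.2, 30))
        tp = transform_intervals(I)
        assert len(tp.estimates) == len(I) - 2


class TestUPOHistogram:
    def test_single_value_single_bin(self):
        hist = upo_histogram(np.full(20, 2.0))
        occupied = hist.relative_frequency > 0
        assert occupied.sum() == 1
        assert hist.relative_frequency.sum() == pytest.approx(1.0)

    def test_edges_are_multiples_of_bin_width(self, rng):
        hist = upo_histogram(np.abs(rng.normal(1.0, 0.3, 100)))
        ratios = hist.bin_edges / 0.05
        np.testing.assert_allclose(ratios, np.round(ratios), atol=1e-9)

    def test_relative_frequency_sums_to_one(self, rng):
        hist = upo_histogram(np.abs(rng.normal(1.5, 0.5, 500)))
        assert hist.relative_frequency.sum() == pytest.approx(1.0)

    def test_bimodal_estimates_recover_two_peaks(self, rng):
        est = np.concatenate([rng.normal(1.0, 0.01, 200), rng.normal(2.5, 0.01, 200)])
        hist = upo_histogram(est)
        centers = hist.bin_centers[hist.relative_frequency > 0.2]
        assert any(abs(c - 1.0) <= 0.05 for c in centers)
        assert any(abs(c - 2.5) <= 0.05 for c in centers)

    def test_no_finite_estimates_errors(self):
        with pytest.raises(ValueError):
            upo_histogram(np.array([np.nan, np.inf]))

    def test_custom_bin_width(self):
        hist = upo_histogram(np.array([0.12, 0.13, 0.14]), bin_width=0.1)
        assert hist.bin_width == 0.1
        assert hist.relative_frequency.sum() == pytest.approx(1.0)


def periodic_intervals(T=0.77, cv=0.05, n=120, seed=0):
    """Near-periodic intervals with crossing-jitter (MA(1)) structure."""
    g = np.random.default_rng(seed)
    e = g.normal(0, cv * T / np.sqrt(2), n + 1)
    return np.abs(T + np.diff(e))


class TestSurrogateSignificance:
    def test_strongly_periodic_intervals_significant(self):
        seq = IntervalSequence(
            periodic_intervals(seed=0), 0.0, "rising", sample_period=0.005
        )
        res = surrogate_significance(seq, n_surrogates=199, seed=1)
        assert res.p_value < 0.05
        assert abs(res.period - 0.77) <= 0.05

    def test_identical_intervals_p_value_one(self):
        seq = IntervalSequence(np.full(30, 1.0), 0.0, "rising", sample_period=0.005)
        res = surrogate_significance(seq, n_surrogates=99, seed=0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_reproducible_under_fixed_seed(self):
        seq = IntervalSequence(
            periodic_intervals(seed=3), 0.0, "rising", sample_period=0.005
        )
        r1 = surrogate_significance(seq, n_surrogates=99, seed=42)
        r2 = surrogate_significance(seq, n_surrogates=99, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.period == r2.period

    def test_too_few_surrogates_errors(self):
        seq = IntervalSequence(periodic_intervals(), 0.0, "rising")
        with pytest.raises(ValueError):
            surrogate_significance(seq, n_surrogates=10)

    def test_envelope_populated(self):
        seq = IntervalSequence(periodic_intervals(seed=5), 0.0, "rising")
        res = surrogate_significance(seq, n_surrogates=49, seed=0)
        hist = res.histogram
        assert hist.surrogate_mean is not None
        assert hist.surrogate_mean.shape == hist.relative_frequency.shape
        assert hist.surrogate_upper is not None

    def test_frequency_is_inverse_period(self):
        seq = IntervalSequence(periodic_intervals(seed=6), 0.0, "rising")
        res = surrogate_significance(seq, n_surrogates=49, seed=0)
        assert res.frequency == pytest.approx(1.0 / res.period)


class TestUPOFromTrace:
    @pytest.mark.parametrize("freq", [0.25, 0.5, 1.3, 1.5])
    def test_noisy_sine_period_recovery(self, freq):
        # period lands within one histogram bin of 1/f despite 10% noise
        rate = 200.0
        t = np.arange(int(60 * rate)) / rate
        rng = np.random.default_rng(17)
        x = np.sin(2 * np.pi * freq * t) + 0.1 * rng.standard_normal(t.size)
        res, seq, _ = upo_from_trace(make_trace(x, rate=rate), seed=0, n_surrogates=99)
        assert abs(res.period - 1.0 / freq) <= 0.05

    def test_returns_detrended_trace(self):
        rate = 200.0
        t = np.arange(int(30 * rate)) / rate
        x = np.sin(2 * np.pi * 1.0 * t) + 0.5 * t  # drift
        _, _, detrended = upo_from_trace(make_trace(x, rate=rate), seed=0, n_surrogates=49)
        assert abs(np.mean(detrended.samples)) < 0.05


class TestLocateSegment:
    def _seq(self, intervals):
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        return IntervalSequence(
            np.asarray(intervals), 0.0, "rising",
            crossing_times=times, sample_period=0.005,
        )

    def test_unique_qualifying_run(self):
        intervals = [2.0, 2.0, 2.0, 3.1, 2.8]
        seq = self._seq(intervals)
        trace = make_trace(np.zeros(int(sum(intervals) * 200) + 10))
        seg = locate_upo_segment(trace, seq, period=2.0, tolerance=0.1)
        assert seg.interval_slice == (0, 3)
        assert seg.start_index == 0
        assert seg.end_index == pytest.approx(6.0 * 200, abs=1)

    def test_all_within_tolerance_spans_everything(self):
        intervals = [2.0, 1.95, 2.05, 2.0]
        seq = self._seq(intervals)
        trace = make_trace(np.zeros(int(sum(intervals) * 200) + 10))
        seg = locate_upo_segment(trace, seq, period=2.0, tolerance=0.1)
        assert seg.interval_slice == (0, 4)

    def test_no_interval_within_tolerance_errors(self):
        seq = self._seq([3.0, 3.1, 2.9])
        trace = make_trace(np.zeros(2000))
        with pytest.raises(ValueError, match="tolerance"):
            locate_upo_segment(trace, seq, period=2.0, tolerance=0.1)

    def test_matches_brute_force_over_all_runs(self, rng):
        period, tol = 2.0, 0.1
        intervals = np.abs(2.0 + np.cumsum(rng.normal(0, 0.08, 40)) * 0.1)
        seq = self._seq(intervals)
        trace = make_trace(np.zeros(int(np.sum(intervals) * 200) + 10))
        seg = locate_upo_segment(trace, seq, period=period, tolerance=tol)
        ok = np.abs(intervals - period) <= tol * period
        assert ok.any()
        # brute force: all contiguous runs entirely within tolerance
        candidates = []
        for a in range(len(intervals)):
            for b in range(a + 1, len(intervals) + 1):
                if ok[a:b].all():
                    candidates.append((a, b))
        best = min(
            candidates,
            key=lambda r: (-(r[1] - r[0]), np.mean(np.abs(intervals[r[0]:r[1]] - period))),
        )
        assert seg.interval_slice == best
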