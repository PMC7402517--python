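"""Periodogram, smoothing, classification and period-estimation behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roachclock import (
    ActivityRecord,
    ArrhythmicError,
    chi_square_periodogram,
    classify_rhythmicity,
    delta_period,
    estimate_period_peaks,
    smooth_periodogram,
)
from roachclock.rhythm import (
    RhythmClassification,
    estimate_period_autocorr,
    significant_peaks,
)
from roachclock.synth import arrhythmic_spec, generate_activity, strong_spec


def sg_truncated_oracle(q, window=11, order=2):
    """Brute-force windowed least-squares quadratic fit (truncated at edges)."""
    n = q.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        idx = np.arange(lo, hi)
        coeffs = np.polyfit(idx - i, q[lo:hi], order)
        out[i] = coeffs[-1]  # value at the centre
    return out


class TestPeakPeriodEstimate:
    @pytest.mark.parametrize("true_period", [24.0, 23.6, 18.85])
    def test_recovers_sinusoid_period(self, true_period):
        t = np.arange(0, 500, 0.01)
        est = estimate_period_peaks(np.sin(2 * np.pi * t / true_period), 0.01, transient_discard=100)
        assert est.period == pytest.approx(true_period, abs=0.01)
        assert est.n_cycles >= 3

    def test_agrees_with_autocorrelation_on_model_output(self, single_traj_500h):
        x3 = single_traj_500h.states[:, 2]
        peaks = estimate_period_peaks(x3, 0.01, transient_discard=100)
        ac = estimate_period_autocorr(x3, 0.01, transient_discard=100)
        assert abs(peaks.period - ac.period) < 0.05

    def test_too_few_cycles_raises(self):
        t = np.arange(0, 260, 0.01)
        with pytest.raises(ArrhythmicError):
            estimate_period_peaks(np.sin(2 * np.pi * t / 30.0), 0.01, transient_discard=200)

    def test_constant_signal_raises(self):
        with pytest.raises(ArrhythmicError):
            estimate_period_peaks(np.ones(50000), 0.01, transient_discard=100)


def square_wave_record(period=24.0, days=7.0, bin_width=0.1, high=100.0):
    t = np.arange(0, days * 24.0, bin_width)
    counts = np.where((t % period) < period / 2, high, 0.0).astype(int)
    return ActivityRecord(times=t, counts=counts, bin_width=bin_width)


class TestChiSquarePeriodogram:
    def test_square_wave_peaks_uniquely_at_true_period(self):
        pg = smooth_periodogram(chi_square_periodogram(square_wave_record(24.0)))
        peaks = significant_peaks(pg)
        assert peaks, "no significant peak found"
        # within one grid step of the true period (smoothing may shift the top by one)
        assert peaks[0][0] == pytest.approx(24.0, abs=0.1 + 1e-9)
        # harmonics/subharmonics of 24 within 18-30 h don't exist, so the peak is unique
        others = [p for p in peaks if abs(p[0] - 24.0) > 0.5]
        assert not others

    def test_constant_record_has_zero_statistic(self):
        t = np.arange(0, 7 * 24, 0.1)
        rec = ActivityRecord(times=t, counts=np.full(t.size, 5), bin_width=0.1)
        pg = chi_square_periodogram(rec)
        assert np.all(pg.statistic == 0.0)
        assert np.all(pg.statistic < pg.threshold)

    def test_statistic_invariant_under_count_shift_and_scale(self):
        rec, _ = generate_activity(strong_spec(seed=11, days=7.0))
        pg = chi_square_periodogram(rec)
        shifted = ActivityRecord(rec.times, rec.counts + 7, rec.bin_width)
        scaled = ActivityRecord(rec.times, rec.counts * 3, rec.bin_width)
        np.testing.assert_allclose(chi_square_periodogram(shifted).statistic, pg.statistic, rtol=1e-9)
        np.testing.assert_allclose(chi_square_periodogram(scaled).statistic, pg.statistic, rtol=1e-9)

    def test_threshold_monotone_in_alpha(self):
        rec, _ = generate_activity(strong_spec(seed=5, days=7.0))
        pg_loose = smooth_periodogram(chi_square_periodogram(rec, alpha=1e-4))
        pg_tight = smooth_periodogram(chi_square_periodogram(rec, alpha=1e-8))
        sig_loose = {p for p, *_ in significant_peaks(pg_loose)}
        sig_tight = {p for p, *_ in significant_peaks(pg_tight)}
        assert sig_tight <= sig_loose

    def test_iid_noise_rarely_significant(self):
        """Small Monte-Carlo type-I check (the full bound is in the acceptance suite)."""
        rng = np.random.default_rng(1234)
        t = np.arange(0, 10 * 24, 0.1)
        hits = 0
        for _ in range(100):
            rec = ActivityRecord(times=t, counts=rng.poisson(30.0, t.size), bin_width=0.1)
            pg = smooth_periodogram(chi_square_periodogram(rec))
            hits += bool(significant_peaks(pg))
        assert hits <= 1

    def test_record_too_short_raises(self):
        t = np.arange(0, 50, 0.1)
        rec = ActivityRecord(times=t, counts=np.ones(t.size, dtype=int), bin_width=0.1)
        with pytest.raises(ValueError, match="two times the longest"):
            chi_square_periodogram(rec)


class TestSavitzkyGolay:
    def test_quadratic_sequence_reproduced_exactly(self):
        idx = np.arange(121)
        q = 3.0 + 0.5 * idx - 0.01 * idx**2
        pg_raw = _pg_from_stat(q)
        sm = smooth_periodogram(pg_raw).smoothed
        np.testing.assert_allclose(sm, q, atol=1e-9)

    def test_constant_sequence_unchanged(self):
        sm = smooth_periodogram(_pg_from_stat(np.full(121, 42.0))).smoothed
        np.testing.assert_allclose(sm, 42.0, atol=1e-10)

    def test_matches_direct_least_squares_oracle(self):
        rng = np.random.default_rng(99)
        q = rng.gamma(5.0, 10.0, size=121)
        sm = smooth_periodogram(_pg_from_stat(q)).smoothed
        np.testing.assert_allclose(sm, sg_truncated_oracle(q), atol=1e-10)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least"):
            smooth_periodogram(_pg_from_stat(np.ones(7)))


def _pg_from_stat(q):
    from roachclock import Periodogram

    periods = 18.0 + 0.1 * np.arange(q.size)
    return Periodogram(periods=periods, statistic=q, threshold=np.full(q.size, 1e9), alpha=1e-6)


class TestClassification:
    def test_strong_single_component_synchronized(self):
        rec, truth = generate_activity(strong_spec(periods=(24.0,), days=10.0, seed=2))
        pg = smooth_periodogram(chi_square_periodogram(rec))
        cls = classify_rhythmicity(pg)
        assert cls.rhythmic and cls.strength == "strong" and cls.synchrony == "synchronized"
        assert cls.dominant_period == pytest.approx(truth["periods"][0], abs=0.1 + 1e-9)

    def test_two_components_desynchronized(self):
        rec, _ = generate_activity(strong_spec(periods=(22.0, 25.0), days=14.0, seed=3))
        pg_full = smooth_periodogram(chi_square_periodogram(rec))
        half = rec.times.size // 2
        seg = ActivityRecord(rec.times[:half], rec.counts[:half], rec.bin_width)
        pg_seg = smooth_periodogram(chi_square_periodogram(seg))
        cls = classify_rhythmicity(pg_full, (pg_seg,))
        assert cls.rhythmic
        assert cls.synchrony == "desynchronized"
        periods = (cls.dominant_period, *cls.secondary_periods)
        assert max(periods) - min(periods) >= 1.0

    def test_without_segment_evidence_not_desynchronized(self):
        rec, _ = generate_activity(strong_spec(periods=(22.0, 25.0), days=14.0, seed=3))
        pg_full = smooth_periodogram(chi_square_periodogram(rec))
        assert classify_rhythmicity(pg_full).synchrony == "synchronized"

    def test_shuffled_record_arrhythmic(self):
        rec, _ = generate_activity(strong_spec(seed=4, days=10.0))
        rng = np.random.default_rng(0)
        shuffled = ActivityRecord(rec.times, rng.permutation(rec.counts), rec.bin_width)
        cls = classify_rhythmicity(smooth_periodogram(chi_square_periodogram(shuffled)))
        assert not cls.rhythmic
        assert cls.dominant_period is None

    def test_unsmoothed_periodogram_rejected(self):
        rec, _ = generate_activity(arrhythmic_spec(seed=1, days=7.0))
        with pytest.raises(ValueError, match="smoothed"):
            classify_rhythmicity(chi_square_periodogram(rec))


class TestDeltaPeriod:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(24.08, 18.85, -5.23), (23.30, 19.83, -3.47), (22.0, 22.0, 0.0)],
    )
    def test_difference_of_dominant_periods(self, before, after, expected):
        mk = lambda p: RhythmClassification(True, "strong", "synchronized", p)
        assert delta_period(mk(before), mk(after)) == pytest.approx(expected, abs=1e-9)

    def test_arrhythmic_side_undefined(self):
        rhythmic = RhythmClassification(True, "strong", "synchronized", 24.0)
        arrhythmic = RhythmClassification(False, "n/a", "synchronized", None)
        with pytest.raises(ArrhythmicError):
            delta_period(rhythmic, arrhythmic)
        with pytest.raises(ArrhythmicError):
            delta_period(arrhythmic, rhythmic)


@settings(max_examples=25, deadline=None)
@given(
    shift=st.floats(-3, 3, allow_nan=False),
    scale=st.floats(0.2, 5, allow_nan=False),
)
def test_qp_invariance_property(shift, scale):
    """Q_P is invariant under affine count transforms with positive scale."""
    rng = np.random.default_rng(7)
    t = np.arange(0, 6 * 24, 0.2)
    base = rng.poisson(20.0, t.size).astype(float)
    rec = ActivityRecord(t, base, 0.2)
    rec2 = ActivityRecord(t, np.maximum(scale * base + abs(shift), 0.0), 0.2)
    q1 = chi_square_periodogram(rec, (18, 26), 0.2).statistic
    q2 = chi_square_periodogram(rec2, (18, 26), 0.2).statistic
    np.testing.assert_allclose(q1, q2, rtol=1e-8)
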