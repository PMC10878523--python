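"""Season-trend decomposition and structural-break detection."""

import numpy as np
import pytest

from firehist.breaks import (MIN_OBSERVATIONS, PixelSeries, TrendBreak,
                             break_confidence_interval, detect_breaks,
                             exhaustive_breakpoints, fit_season_trend)

MONTHS = np.arange(300)


def seasonal(months, mean=0.7, amp=0.06, peak=2.0):
    return mean + amp * np.cos(2 * np.pi * (months - peak) / 12.0)


class TestFit:
    def test_pure_sinusoid_flat_trend_amplitude_recovered(self):
        y = seasonal(MONTHS, amp=0.1)
        fit = fit_season_trend(PixelSeries(MONTHS, y), harmonic_order=2)
        assert fit.breakpoints == ()
        (a, b), = fit.segment_coefs
        assert abs(b) < 1e-8
        amp = np.hypot(fit.season_coef[0], fit.season_coef[1])
        assert amp == pytest.approx(0.1, rel=0.01)

    def test_constant_series_zero_everything(self):
        y = np.full(60, 0.5)
        fit = fit_season_trend(PixelSeries(np.arange(60), y))
        assert fit.breakpoints == ()
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.season_coef, 0.0, atol=1e-8)

    def test_level_drop_makes_two_segments(self):
        y = seasonal(MONTHS) - 0.4 * (MONTHS >= 200)
        fit = fit_season_trend(PixelSeries(MONTHS, y))
        assert fit.n_segments == 2
        assert fit.breakpoints == (199,)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_season_trend(PixelSeries(np.arange(10), np.ones(10)))
        assert MIN_OBSERVATIONS == 24

    def test_gaps_are_fit_on_observed_dates_only(self):
        rng = np.random.default_rng(2)
        keep = rng.random(300) > 0.2
        y = seasonal(MONTHS) - 0.4 * (MONTHS >= 200)
        fit = fit_season_trend(PixelSeries(MONTHS[keep], y[keep]))
        brks = detect_breaks(fit)
        assert len(brks) == 1 and abs(brks[0].month - 200) <= 2


class TestDetect:
    def test_no_break_false_positive_rate(self):
        fp = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            y = seasonal(MONTHS) + rng.normal(0, 0.02, len(MONTHS))
            if detect_breaks(fit_season_trend(PixelSeries(MONTHS, y))):
                fp += 1
        assert fp <= 5  # empty in >= 95% of replicates

    def test_single_drop_recovered_with_dating(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            y = seasonal(MONTHS) - 0.4 * (MONTHS >= 200) \
                + rng.normal(0, 0.05, len(MONTHS))
            brks = detect_breaks(fit_season_trend(PixelSeries(MONTHS, y)))
            neg = [b for b in brks if b.sign < 0]
            if len(neg) == 1 and abs(neg[0].month - 200) <= 2:
                hits += 1
        assert hits >= 95

    def test_two_distant_drops_order_preserved(self):
        ok = 0
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            y = seasonal(MONTHS) - 0.4 * (MONTHS >= 120) - 0.3 * (MONTHS >= 220) \
                + rng.normal(0, 0.05, len(MONTHS))
            brks = detect_breaks(fit_season_trend(PixelSeries(MONTHS, y)))
            neg = [b.month for b in brks if b.sign < 0]
            if len(neg) == 2 and neg == sorted(neg) \
                    and abs(neg[0] - 120) <= 2 and abs(neg[1] - 220) <= 2:
                ok += 1
        assert ok >= 18

    def test_magnitude_and_sign(self):
        y = seasonal(MONTHS) - 0.4 * (MONTHS >= 200)
        brk, = detect_breaks(fit_season_trend(PixelSeries(MONTHS, y)))
        assert brk.sign < 0
        assert brk.magnitude == pytest.approx(-0.4, abs=0.02)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(7)
        y = seasonal(MONTHS) - 0.4 * (MONTHS >= 200) + rng.normal(0, 0.03, 300)
        b1, = detect_breaks(fit_season_trend(PixelSeries(MONTHS, y)))
        b2, = detect_breaks(fit_season_trend(PixelSeries(MONTHS, y + 5.0)))
        assert b1.month == b2.month
        assert b1.magnitude == pytest.approx(b2.magnitude, abs=1e-6)


class TestConfidenceInterval:
    def test_noiseless_step_ci_collapses(self):
        y = seasonal(MONTHS) - 0.4 * (MONTHS >= 200)
        brk, = detect_breaks(fit_season_trend(PixelSeries(MONTHS, y)))
        assert brk.ci == (200, 200)

    def test_nesting_of_levels(self):
        rng = np.random.default_rng(9)
        y = seasonal(MONTHS) - 0.2 * (MONTHS >= 200) + rng.normal(0, 0.08, 300)
        fit = fit_season_trend(PixelSeries(MONTHS, y))
        if not fit.breakpoints:
            pytest.skip("no break found at this noise draw")
        lo95, hi95 = break_confidence_interval(fit, 0, level=0.95)
        lo99, hi99 = break_confidence_interval(fit, 0, level=0.99)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_ci_width_monotone_in_noise(self):
        widths = []
        for sd in (0.02, 0.05, 0.1):
            total = 0
            for s in range(50):
                rng = np.random.default_rng(s)
                y = seasonal(MONTHS) - 0.25 * (MONTHS >= 200) \
                    + rng.normal(0, sd, 300)
                fit = fit_season_trend(PixelSeries(MONTHS, y))
                if fit.breakpoints:
                    lo, hi = break_confidence_interval(fit, 0)
                    total += hi - lo
            widths.append(total / 50)
        assert widths[0] <= widths[1] <= widths[2]

    def test_ci_contains_break(self):
        rng = np.random.default_rng(12)
        y = seasonal(MONTHS) - 0.3 * (MONTHS >= 150) + rng.normal(0, 0.05, 300)
        brk, = detect_breaks(fit_season_trend(PixelSeries(MONTHS, y)))
        assert brk.ci[0] <= brk.month <= brk.ci[1]


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_breaks", [1, 2])
    def test_dp_matches_exhaustive_search_small_series(self, n_breaks):
        for s in range(10):
            rng = np.random.default_rng(100 * n_breaks + s)
            n = int(rng.integers(40, 61))
            m = np.arange(n)
            y = rng.normal(0, 0.1, n)
            for b in sorted(rng.choice(np.arange(10, n - 10), n_breaks,
                                       replace=False)):
                y[b:] -= rng.uniform(0.2, 0.5)
            fit = fit_season_trend(PixelSeries(m, y), harmonic_order=0,
                                   max_breaks=n_breaks)
            rss_bf, bp_bf = exhaustive_breakpoints(
                m.astype(float), fit.deseasonalised, n_breaks, fit.min_len)
            assert fit.rss_by_k[n_breaks] == pytest.approx(rss_bf, rel=1e-9)
            assert tuple(fit.bp_by_k[n_breaks, :n_breaks]) == bp_bf


class TestPixelSeries:
    def test_nonmonotone_dates_rejected(self):
        with pytest.raises(ValueError):
            PixelSeries(np.array([1, 3, 2]), np.zeros(3))

    def test_missing_values_dropped(self):
        s = PixelSeries(np.arange(5), np.array([1.0, np.nan, 2.0, np.nan, 3.0]))
        assert len(s) == 3
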