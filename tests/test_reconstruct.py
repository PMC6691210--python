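import numpy as np
import pytest
from scipy.stats import norm

from runtiming.reconstruct import (SurveyRecord, YearExcludedError,
                                   fit_entry_cdf, fit_entry_cdf_batch,
                                   fit_entry_distribution, interpolate_daily,
                                   percentiles_from_normal,
                                   reconstruct_entries, spawning_distribution,
                                   timing_percentiles)
from runtiming.series import DailySeries, StreamLifeSchedule


class TestInterpolation:
    def test_midpoint_between_surveys(self):
        surveys = [SurveyRecord(2000, 250, 0.0),
                   SurveyRecord(2000, 254, 8.0),
                   SurveyRecord(2000, 258, 0.0)]
        daily = interpolate_daily(surveys)
        assert daily.value_on(252) == 4.0
        assert daily.value_on(254) == 8.0

    def test_pads_zero_day_before_and_after(self):
        surveys = [SurveyRecord(2000, 250, 4.0),
                   SurveyRecord(2000, 252, 8.0),
                   SurveyRecord(2000, 254, 4.0)]
        daily = interpolate_daily(surveys)
        assert daily.first_day == 249
        assert daily.value_on(249) == 0.0
        assert daily.value_on(255) == 0.0

    def test_too_few_surveys_excludes_year(self):
        with pytest.raises(YearExcludedError, match="2 surveys"):
            interpolate_daily([SurveyRecord(2000, 250, 1.0),
                               SurveyRecord(2000, 254, 1.0)])

    def test_rejects_unsorted_days(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            interpolate_daily([SurveyRecord(2000, 254, 1.0),
                               SurveyRecord(2000, 250, 1.0),
                               SurveyRecord(2000, 258, 1.0)])

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            interpolate_daily([SurveyRecord(2000, 250, 1.0),
                               SurveyRecord(2000, 254, -1.0),
                               SurveyRecord(2000, 258, 1.0)])

    def test_rejects_mixed_years(self):
        with pytest.raises(ValueError, match="multiple years"):
            interpolate_daily([SurveyRecord(2000, 250, 1.0),
                               SurveyRecord(2001, 254, 1.0),
                               SurveyRecord(2000, 258, 1.0)])


class TestEntriesRecursion:
    def test_hand_example_constant_stream_life(self):
        # live counts under L = 2: entrants [10, 6, 6, -2, 2]
        live = DailySeries(2000, 100, [10.0, 16.0, 12.0, 4.0, 0.0])
        sched = StreamLifeSchedule(2.0, 2.0)
        entries = reconstruct_entries(live, sched)
        assert list(entries.values) == [10.0, 6.0, 6.0, -2.0, 2.0]

    def test_conservation_total_entries_pass_through(self):
        # occupancy that returns to zero: total entries equal total deaths,
        # so the running sum of entries ends at zero occupancy
        rng = np.random.default_rng(5)
        true = DailySeries(2000, 100, rng.integers(0, 30, size=12).astype(float))
        sched = StreamLifeSchedule(4.0, 4.0)
        from runtiming.simulate import forward_live_counts
        live = forward_live_counts(true, sched)
        rec = reconstruct_entries(live, sched)
        assert rec.total == pytest.approx(true.total)

    def test_inverts_declining_stream_life_forward_model(self):
        from runtiming.simulate import forward_live_counts
        rng = np.random.default_rng(11)
        true = DailySeries(2000, 200, rng.integers(0, 50, 20).astype(float))
        sched = StreamLifeSchedule(9.0, 4.0, anchor_start_day=200,
                                   anchor_end_day=219)
        live = forward_live_counts(true, sched)
        rec = reconstruct_entries(live, sched)
        recovered = np.array([rec.value_on(d) for d in true.days])
        assert np.allclose(recovered, true.values)


class TestCdfFit:
    def test_recovers_normal_entries_exactly(self):
        days = np.arange(240, 301)
        pmf = np.diff(norm.cdf(np.concatenate(([days[0] - 0.5],
                                               days + 0.5)), 270.0, 10.0))
        entries = DailySeries(2000, 240, 1000 * pmf)
        mu, sigma, sse = fit_entry_cdf(entries)
        assert mu == pytest.approx(270.0, abs=0.1)
        assert sigma == pytest.approx(10.0, abs=0.2)

    def test_point_mass_hits_sigma_floor(self):
        entries = DailySeries(2000, 268, [0.0, 0.0, 100.0, 0.0, 0.0])
        mu, sigma, sse = fit_entry_cdf(entries)
        assert abs(mu - 270.0) < 1.0
        assert sigma == pytest.approx(0.5, abs=0.1)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        vals = np.maximum(rng.normal(10, 3, 41), 0.0)
        a = DailySeries(2000, 230, vals)
        b = DailySeries(2000, 250, vals)
        mu_a, s_a, _ = fit_entry_cdf(a)
        mu_b, s_b, _ = fit_entry_cdf(b)
        assert mu_b - mu_a == pytest.approx(20.0, abs=1e-6)
        assert s_b == pytest.approx(s_a, abs=1e-6)

    def test_rejects_nonpositive_total(self):
        with pytest.raises(ValueError, match="positive"):
            fit_entry_cdf(DailySeries(2000, 250, [1.0, -2.0]))

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(9)
        days = np.arange(240, 301).astype(float)
        curves = []
        expected = []
        for k in range(12):
            mu_t = 255 + 30 * rng.random()
            sd_t = 5 + 10 * rng.random()
            vals = np.diff(norm.cdf(np.concatenate(([days[0] - 0.5],
                                                    days + 0.5)), mu_t, sd_t))
            vals = np.maximum(vals * 1000 + rng.normal(0, 5, len(days)), 0)
            series = DailySeries(2000, 240, vals)
            mu_s, sd_s, _ = fit_entry_cdf(series)
            expected.append((mu_s, sd_s))
            curves.append(np.cumsum(vals) / vals.sum())
        mu_b, sd_b = fit_entry_cdf_batch(days, np.array(curves))
        exp = np.array(expected)
        assert np.allclose(mu_b, exp[:, 0], atol=1e-5)
        assert np.allclose(sd_b, exp[:, 1], atol=1e-5)


class TestTiming:
    def test_percentiles_first_day_strictly_exceeding(self):
        daily = DailySeries(2000, 1, [1.0, 2.0, 3.0, 4.0])
        ts = timing_percentiles(daily, (10, 50, 90))
        assert ts.dates[50] == 3.0  # cumulative 0.1, 0.3, 0.6, 1.0
        assert ts.dates[10] == 2.0
        assert ts.dates[90] == 4.0
        assert ts.duration == 2.0

    def test_percentiles_require_positive_total(self):
        with pytest.raises(ValueError, match="positive"):
            timing_percentiles(DailySeries(2000, 1, [0.0, 0.0]))

    def test_normal_percentiles_are_symmetric(self):
        ts = percentiles_from_normal(270.0, 10.0, (10, 50, 90))
        assert ts.dates[50] == pytest.approx(270.0)
        assert ts.dates[90] - 270.0 == pytest.approx(270.0 - ts.dates[10])

    def test_spawning_distribution_adds_delay(self):
        entry = fit_entry_distribution(
            DailySeries(2000, 260, np.full(21, 10.0)))
        spawn = spawning_distribution(entry, 8.0)
        assert spawn.mu == pytest.approx(entry.mu + 8.0)
        assert spawn.sigma == entry.sigma

    def test_spawning_delay_range_enforced(self):
        entry = fit_entry_distribution(
            DailySeries(2000, 260, np.full(21, 10.0)))
        with pytest.raises(ValueError, match="delay"):
            spawning_distribution(entry, 31.0)
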