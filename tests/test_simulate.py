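import numpy as np
import pytest

from runtiming.covariates import september_cum_increase
from runtiming.reconstruct import fit_entry_cdf, interpolate_daily, \
    reconstruct_entries
from runtiming.series import DailySeries, StreamLifeSchedule
from runtiming.simulate import (EnvConfig, ScenarioConfig,
                                forward_live_counts, generate_environment,
                                generate_hatchery, generate_run,
                                generate_timing_series)


class TestForwardModel:
    def test_conservation_exact(self):
        rng = np.random.default_rng(2)
        entries = DailySeries(2000, 250, rng.integers(0, 40, 15).astype(float))
        live = forward_live_counts(entries, StreamLifeSchedule(6.0, 6.0))
        # every fish is alive for exactly 6 days
        assert live.total == pytest.approx(6.0 * entries.total)

    def test_single_cohort_occupancy(self):
        entries = DailySeries(2000, 250, [100.0])
        live = forward_live_counts(entries, StreamLifeSchedule(3.0, 3.0))
        assert list(live.values) == [100.0, 100.0, 100.0]

    def test_round_trip_many_stream_lives(self):
        rng = np.random.default_rng(8)
        for L in range(10, 26, 5):
            entries = DailySeries(2000, 240,
                                  rng.integers(0, 80, 30).astype(float))
            sched = StreamLifeSchedule(float(L), float(L))
            rec = reconstruct_entries(forward_live_counts(entries, sched),
                                      sched)
            recovered = np.array([rec.value_on(d) for d in entries.days])
            assert np.array_equal(recovered, entries.values), f"L={L}"


class TestGenerateRun:
    def test_run_size_is_exact(self):
        cfg = ScenarioConfig(first_year=1991, last_year=1991,
                             run_size=12_345, seed=3)
        rd = generate_run(cfg, 1991)
        assert rd.true_entries.total == 12_345

    def test_seed_determinism_and_distinctness(self):
        a = generate_run(ScenarioConfig(run_size=5_000, seed=4), 1995)
        b = generate_run(ScenarioConfig(run_size=5_000, seed=4), 1995)
        c = generate_run(ScenarioConfig(run_size=5_000, seed=5), 1995)
        assert np.array_equal(a.true_entries.values, b.true_entries.values)
        assert [s.live_count for s in a.surveys] == \
               [s.live_count for s in b.surveys]
        assert not np.array_equal(a.true_entries.values,
                                  c.true_entries.values)

    def test_year_outside_range_rejected(self):
        cfg = ScenarioConfig(first_year=1991, last_year=1994)
        with pytest.raises(ValueError, match="outside configured range"):
            generate_run(cfg, 1990)

    def test_surveys_cover_live_window(self):
        cfg = ScenarioConfig(run_size=20_000, seed=1)
        rd = generate_run(cfg, 2000)
        days = [s.day for s in rd.surveys]
        assert days[0] <= rd.live.first_day
        assert days[-1] >= rd.live.last_day
        assert all(d2 > d1 for d1, d2 in zip(days, days[1:]))

    def test_noise_free_surveys_match_live_counts(self):
        cfg = ScenarioConfig(run_size=20_000, survey_cv=0.0, seed=1)
        rd = generate_run(cfg, 2000)
        for s in rd.surveys:
            assert s.live_count == rd.live.value_on(s.day)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="h2_true"):
            ScenarioConfig(h2_true=1.5)
        with pytest.raises(ValueError, match="entry mean"):
            ScenarioConfig(entry_mean=30.0)
        with pytest.raises(ValueError, match="final stream-life"):
            ScenarioConfig(stream_life_initial=10.0, stream_life_final=12.0)


class TestHatchery:
    def test_full_season_weir_gives_zero_differential(self):
        cfg = ScenarioConfig(first_year=2000, last_year=2000,
                             run_size=200_000, weir_open=1, weir_close=365,
                             hatchery_fraction=1.0, seed=2)
        rd = generate_run(cfg, 2000)
        hd = generate_hatchery(cfg, 2000, rd.true_entries)
        # trapping everything leaves hatchery mean = population mean
        assert hd.true_raw_differential == pytest.approx(0.0, abs=0.05)

    def test_weir_closing_at_median_selects_early(self):
        cfg = ScenarioConfig(first_year=2000, last_year=2000,
                             run_size=200_000, seed=2)   # closes ~60th pctile
        rd = generate_run(cfg, 2000)
        hd = generate_hatchery(cfg, 2000, rd.true_entries)
        assert hd.true_raw_differential < -2.0

    def test_egg_take_day_is_trap_day_plus_delay(self):
        cfg = ScenarioConfig(first_year=2000, last_year=2000,
                             run_size=100_000, seed=6)
        rd = generate_run(cfg, 2000)
        hd = generate_hatchery(cfg, 2000, rd.true_entries)
        assert hd.egg_take.first_day >= cfg.weir_open + 8
        assert hd.egg_take.last_day <= cfg.weir_close + 8

    def test_otoliths_have_two_age_classes_and_group_labels(self):
        cfg = ScenarioConfig(first_year=2000, last_year=2000,
                             run_size=100_000, seed=6)
        rd = generate_run(cfg, 2000)
        hd = generate_hatchery(cfg, 2000, rd.true_entries)
        oto = hd.otoliths
        assert set(oto["age"].unique()) == {4, 5}
        assert set(oto["return_year"].unique()) == {2004, 2005}
        assert set(oto["parental_group"]) <= {"early", "middle", "late"}

    def test_empty_weir_window_warns(self):
        cfg = ScenarioConfig(first_year=2000, last_year=2000,
                             run_size=10_000, weir_open=1, weir_close=30,
                             seed=6)
        rd = generate_run(cfg, 2000)
        with pytest.warns(UserWarning, match="no fish"):
            hd = generate_hatchery(cfg, 2000, rd.true_entries)
        assert np.isnan(hd.true_raw_differential)


class TestEnvironment:
    def test_deterministic_without_noise(self):
        env = EnvConfig(temp_noise_sd=0.0, flow_noise_cv=0.0,
                        freshet_rate_sep=0.0)
        cfg = ScenarioConfig(env=env, seed=1)
        flow, temp = generate_environment(cfg, 1991)
        flow2, temp2 = generate_environment(cfg, 1991)
        assert np.array_equal(flow.values, flow2.values)
        assert np.array_equal(temp.values, temp2.values)
        # the noiseless seasonal flow rises monotonically through
        # September (toward the winter peak), so the cumulative increase
        # is exactly the start-to-end rise
        from runtiming.covariates import SEP1, SEP30
        sept = september_cum_increase(flow)
        assert sept == pytest.approx(flow.value_on(SEP30)
                                     - flow.value_on(SEP1))

    def test_temperature_trend_recovered(self):
        env = EnvConfig(temp_noise_sd=0.0, temp_trend=0.05)
        cfg = ScenarioConfig(first_year=1971, last_year=2011, env=env)
        _, t0 = generate_environment(cfg, 1971)
        _, t1 = generate_environment(cfg, 2011)
        assert np.mean(t1.values - t0.values) == pytest.approx(2.0, abs=0.01)

    def test_freshet_break_reduces_september_increase(self):
        env = EnvConfig(freshet_break_year=2000, freshet_break_factor=0.2,
                        flow_noise_cv=0.0)
        cfg = ScenarioConfig(first_year=1991, last_year=2010, env=env)
        pre = np.mean([september_cum_increase(
            generate_environment(cfg, y)[0]) for y in range(1991, 2000)])
        post = np.mean([september_cum_increase(
            generate_environment(cfg, y)[0]) for y in range(2000, 2010)])
        assert post < pre


class TestTimingSeries:
    def test_pure_kink_shape(self):
        ts = generate_timing_series(45, 280.0, 0.0, break_index=25,
                                    shift_per_year=-1.26)
        assert ts.iloc[0] == 280.0
        assert ts.iloc[25] == 280.0
        assert ts.iloc[26] == pytest.approx(280.0 - 1.26)
        assert ts.iloc[44] == pytest.approx(280.0 - 19 * 1.26)

    def test_level_shift_shape(self):
        ts = generate_timing_series(45, 280.0, 0.0, break_index=25,
                                    level_shift=-10.0)
        assert ts.iloc[25] == 280.0 and ts.iloc[26] == 270.0

    def test_seeded_noise_is_reproducible(self):
        a = generate_timing_series(30, 280.0, 2.0, seed=3)
        b = generate_timing_series(30, 280.0, 2.0, seed=3)
        assert a.equals(b)
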