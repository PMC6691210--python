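"""Synthetic sockeye run, hatchery, and environment generator.

Produces datasets with known ground truth and the same statistical
structure the analysis stages assume: a latent normal river-entry
distribution per year, live-count surveys every few days with
multiplicative noise, a hatchery weir that misses the earliest and latest
fish, egg-take schedules, thermally-marked parental timing groups with
heritable spawn timing, and daily flow/temperature series with trends and
breaks. The infinitesimal-model shift (offspring deviate from the
population mean by h² times the parental deviation) is all the genetics
the breeder's-equation context requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .heritability import tercile_group_means
from .reconstruct import SurveyRecord
from .series import DailySeries, StreamLifeSchedule

# rng stream ids so each component is independent and reproducible
_RUN, _SURVEY, _HATCHERY, _OTOLITH, _ENV, _YEAR_EFFECT = range(6)

GROUPS = ("early", "middle", "late")


@dataclass
class EnvConfig:
    """Daily temperature and discharge generator settings.

    Temperature is a seasonal sinusoid (°C) plus a linear warming trend
    and AR(1) noise. Discharge (m³/s) is a seasonal baseline plus
    autocorrelated multiplicative noise and rainfall freshet spikes whose
    September frequency can trend or break between years.
    """

    temp_base: float = 10.0
    temp_amp: float = 8.0
    temp_peak_day: int = 213          # around Aug 1
    temp_trend: float = 0.02          # °C per year
    temp_noise_sd: float = 0.8
    flow_base: float = 15.0
    flow_amp: float = 10.0
    flow_peak_day: int = 20           # mid-winter baseline peak
    flow_noise_cv: float = 0.15
    freshet_rate_sep: float = 0.12    # spikes per day, Aug-Oct
    freshet_rate_trend: float = 0.0   # multiplicative per year (log scale)
    freshet_break_year: int | None = None
    freshet_break_factor: float = 0.5
    freshet_scale: float = 40.0       # mean spike size, m³/s


@dataclass
class ScenarioConfig:
    """One simulated study: the generator's defaults are the reference
    study's point estimates (stream-life 18→11 days with a −2 day between-year
    trend, 8-day spawning delay, 93%/17% hatchery/natural egg-to-fry
    survival, 14% of the return trapped) and survey effort of one count
    every ~4–10 days."""

    first_year: int = 1991
    last_year: int = 2015
    entry_mean: float | dict[int, float] = 270.0     # day-of-year
    entry_sd: float = 10.0
    run_size: int | dict[int, int] = field(
        default_factory=lambda: {"pre2007": 250_000, "post2007": 75_000})
    stream_life_initial: float = 18.0
    stream_life_final: float = 11.0
    stream_life_trend: float = -2.0    # total days over the year span
    spawning_delay: float = 8.0
    survey_interval: int = 7           # mean gap, days
    survey_cv: float = 0.15
    weir_open: int = 245
    weir_close: int = 273              # ~60th percentile of N(270, 10)
    hatchery_fraction: float = 0.14
    h2_true: float = 0.8
    egg_to_fry_hatchery: float = 0.93
    egg_to_fry_natural: float = 0.17
    fecundity: int = 3200
    otolith_samples_per_year: int = 1200
    offspring_noise_sd: float = 5.0    # individual spawn-date noise, days
    year_effect_sd: float = 1.0        # shared return-year shift, days
    age4_prob: float = 0.8
    env: EnvConfig = field(default_factory=EnvConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hatchery_fraction", "h2_true", "egg_to_fry_hatchery",
                     "egg_to_fry_natural", "age4_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.stream_life_final > self.stream_life_initial:
            raise ValueError("final stream-life must not exceed initial")
        if self.last_year < self.first_year:
            raise ValueError("year range is empty")
        for y in self.years:
            m = self.entry_mean_for(y)
            if not 180 <= m <= 365:
                raise ValueError(f"entry mean {m} outside [180, 365]")
            if self.run_size_for(y) <= 0:
                raise ValueError("run size must be positive")

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    def entry_mean_for(self, year: int) -> float:
        if isinstance(self.entry_mean, dict):
            return float(self.entry_mean[year])
        return float(self.entry_mean)

    def run_size_for(self, year: int) -> int:
        if isinstance(self.run_size, dict):
            if year in self.run_size:
                return int(self.run_size[year])
            return int(self.run_size["pre2007"] if year < 2007
                       else self.run_size["post2007"])
        return int(self.run_size)

    def schedule(self) -> StreamLifeSchedule:
        return StreamLifeSchedule(self.stream_life_initial,
                                  self.stream_life_final,
                                  self.stream_life_trend)

    def schedule_for_year(self, year: int) -> StreamLifeSchedule:
        return self.schedule().for_year(year, self.first_year, self.last_year)

    def _rng(self, year: int, component: int) -> np.random.Generator:
        return np.random.default_rng(
            [int(self.seed) % (2**31), int(year), int(component)])


@dataclass
class RunData:
    """One year's simulated run: the truth and its observables."""

    year: int
    true_entries: DailySeries
    live: DailySeries
    surveys: list[SurveyRecord]
    schedule: StreamLifeSchedule   # per-year, anchored to the true entry span


def _entry_pmf(mu: float, sd: float) -> tuple[int, np.ndarray]:
    from scipy.stats import norm
    lo = max(1, int(np.floor(mu - 5 * sd)))
    hi = min(365, int(np.ceil(mu + 5 * sd)))
    edges = np.arange(lo, hi + 2) - 0.5
    pmf = np.diff(norm.cdf(edges, loc=mu, scale=sd))
    return lo, pmf / pmf.sum()


def generate_run(config: ScenarioConfig, year: int) -> RunData:
    """Draw a year's daily entries, forward-simulate live counts under the
    cohort stream-life schedule, and sample noisy sparse surveys."""
    if year not in config.years:
        raise ValueError(f"year {year} outside configured range")
    rng = config._rng(year, _RUN)
    size = config.run_size_for(year)
    lo, pmf = _entry_pmf(config.entry_mean_for(year), config.entry_sd)
    counts = rng.multinomial(size, pmf).astype(float)
    entries = DailySeries(year, lo, counts).trimmed()

    sched = config.schedule_for_year(year)
    sched = replace(sched, anchor_start_day=entries.first_day,
                    anchor_end_day=entries.last_day)
    live = forward_live_counts(entries, sched)
    surveys = _sample_surveys(config, year, live)
    return RunData(year, entries, live, surveys, sched)


def forward_live_counts(entries: DailySeries,
                        schedule: StreamLifeSchedule) -> DailySeries:
    """Cohort bookkeeping: entrants on day d stay alive for their cohort's
    stream-life, so live(t) = sum of entrants with d <= t < death day.

    This is the forward model whose inversion is the deaths/entries
    recursion in :mod:`runtiming.reconstruct`.
    """
    a0 = schedule.anchor_start_day or entries.first_day
    a1 = schedule.anchor_end_day or entries.last_day
    offsets = schedule.death_offset(entries.days, a0, a1)
    n = len(entries.values) + int(offsets.max())
    delta = np.zeros(n + 1)
    idx = np.arange(len(entries.values))
    np.add.at(delta, idx, entries.values)
    np.add.at(delta, idx + offsets, -entries.values)
    live = np.cumsum(delta[:-1])
    return DailySeries(entries.year, entries.first_day, live).trimmed()


def _sample_surveys(config: ScenarioConfig, year: int,
                    live: DailySeries) -> list[SurveyRecord]:
    rng = config._rng(year, _SURVEY)
    gap_lo = max(1, config.survey_interval - 3)
    gap_hi = config.survey_interval + 3
    day = max(1, live.first_day - 2)
    last = min(366, live.last_day + 2)
    days = [day]
    while days[-1] < last:
        days.append(min(last, days[-1] + int(rng.integers(gap_lo, gap_hi + 1))))
    if config.survey_cv > 0:
        s = np.sqrt(np.log1p(config.survey_cv ** 2))
        noise = rng.lognormal(-0.5 * s * s, s, size=len(days))
    else:
        noise = np.ones(len(days))
    return [SurveyRecord(year, d, live.value_on(d) * f)
            for d, f in zip(days, noise)]


@dataclass
class HatcheryData:
    """One brood year of hatchery operations and marked offspring."""

    year: int
    egg_take: DailySeries            # eggs fertilized per day
    females_by_day: DailySeries
    n_trapped: int
    group_means: dict[str, float]    # egg-weighted mean spawn day per mark
    otoliths: pd.DataFrame           # return_year, spawn_date, age, parental_group
    true_raw_differential: float     # hatchery minus whole-population mean, days
    natural_mean_spawn: float


def generate_hatchery(config: ScenarioConfig, year: int,
                      true_entries: DailySeries) -> HatcheryData:
    """Trap a binomial share of entrants inside the weir window, schedule
    egg takes at trap date + spawning delay, assign early/middle/late
    thermal-mark groups by egg-take terciles, and draw returning offspring
    whose spawn dates shift by h² times the parental-group deviation."""
    rng = config._rng(year, _HATCHERY)
    days = true_entries.days
    in_window = (days >= config.weir_open) & (days <= config.weir_close)
    delay = int(round(config.spawning_delay))

    eligible = true_entries.values[in_window].astype(int)
    if eligible.sum() == 0:
        warnings.warn(f"{year}: weir window caught no fish; zero egg take")
        trapped = np.zeros(0, dtype=int)
        trap_days = np.zeros(0, dtype=int)
    else:
        trapped = rng.binomial(eligible, config.hatchery_fraction)
        trap_days = days[in_window]

    n_trapped = int(trapped.sum())
    take_days = trap_days + delay
    females = rng.binomial(trapped, 0.5) if n_trapped else trapped
    eggs = females.astype(float) * config.fecundity

    if n_trapped and eggs.sum() > 0:
        first = int(take_days[0])
        width = int(take_days[-1]) - first + 1
        egg_vals = np.zeros(width)
        fem_vals = np.zeros(width)
        egg_vals[take_days - first] = eggs
        fem_vals[take_days - first] = females
        egg_take = DailySeries(year, first, egg_vals)
        females_by_day = DailySeries(year, first, fem_vals)
        group_means = tercile_group_means(egg_take)
        hatchery_mean = float(np.average(egg_take.days,
                                         weights=egg_take.values))
    else:
        egg_take = DailySeries(year, config.weir_open + delay, np.zeros(1))
        females_by_day = DailySeries(year, config.weir_open + delay,
                                     np.zeros(1))
        group_means = {}
        hatchery_mean = np.nan

    # population truth for the ground-truth table
    pop_entry_mean = float(np.average(days, weights=true_entries.values))
    pop_mean = pop_entry_mean + config.spawning_delay
    p = n_trapped / true_entries.total if true_entries.total else 0.0
    natural_mean = ((pop_mean - p * hatchery_mean) / (1 - p)
                    if (n_trapped and p < 1) else pop_mean)
    raw = hatchery_mean - pop_mean if n_trapped else np.nan

    otoliths = _draw_otoliths(config, year, group_means, egg_take, pop_mean)
    return HatcheryData(year, egg_take, females_by_day, n_trapped,
                        group_means, otoliths, raw, natural_mean)


_AGE_EFFECT = {4: 1.5, 5: -1.5}   # younger fish spawn a bit later


def _draw_otoliths(config: ScenarioConfig, year: int,
                   group_means: dict[str, float], egg_take: DailySeries,
                   pop_mean: float) -> pd.DataFrame:
    if not group_means:
        return pd.DataFrame(columns=["return_year", "spawn_date", "age",
                                     "parental_group"])
    rng = config._rng(year, _OTOLITH)
    n = config.otolith_samples_per_year
    names = [g for g in GROUPS if g in group_means]
    # offspring sampled in proportion to each group's egg share
    shares = _group_egg_shares(egg_take, names)
    groups = rng.choice(len(names), size=n, p=shares)
    ages = np.where(rng.random(n) < config.age4_prob, 4, 5)
    year_eff = {a: float(config._rng(year + a, _YEAR_EFFECT)
                         .normal(0.0, config.year_effect_sd))
                for a in (4, 5)}
    devs = np.array([group_means[g] - pop_mean for g in names])
    # Group-level environmental deviation keeping the offspring-generation
    # phenotypic variance equal to the parental one (stationary variance):
    # var(offspring group mean) = h4*var(dev) + (1-h4)*var(dev). Without
    # it, group means would be almost perfectly correlated across
    # generations and the realized-h2 slope would estimate ~1 regardless
    # of the true heritability.
    h2 = config.h2_true
    eta_sd = float(devs.std(ddof=0)) * np.sqrt(max(0.0, 1.0 - h2 * h2))
    eta = {(g, a): float(rng.normal(0.0, eta_sd))
           for g in range(len(names)) for a in (4, 5)}
    parent_dev = devs[groups]
    dates = (pop_mean
             + h2 * parent_dev
             + np.array([eta[(g, a)] for g, a in zip(groups, ages)])
             + np.array([_AGE_EFFECT[a] for a in ages])
             + np.array([year_eff[a] for a in ages])
             + rng.normal(0.0, config.offspring_noise_sd, size=n))
    return pd.DataFrame({
        "return_year": year + ages,
        "spawn_date": np.rint(dates).astype(int),
        "age": ages,
        "parental_group": [names[g] for g in groups],
    })


def _group_egg_shares(egg_take: DailySeries, names: list[str]) -> np.ndarray:
    cum = np.cumsum(egg_take.values)
    total = cum[-1]
    bounds = (cum - 1e-9) // (total / 3)
    shares = []
    for g, name in enumerate(GROUPS):
        if name in names:
            shares.append(egg_take.values[bounds == g].sum())
    shares = np.array(shares, dtype=float)
    return shares / shares.sum()


def generate_environment(config: ScenarioConfig,
                         year: int) -> tuple[DailySeries, DailySeries]:
    """Daily discharge and water temperature for one calendar year."""
    env = config.env
    rng = config._rng(year, _ENV)
    d = np.arange(1, 366)
    dy = year - config.first_year

    temp = (env.temp_base + env.temp_trend * dy
            + env.temp_amp * np.cos(2 * np.pi * (d - env.temp_peak_day) / 365))
    if env.temp_noise_sd > 0:
        temp = temp + _ar1(rng, len(d), env.temp_noise_sd, 0.7)

    flow = (env.flow_base
            + env.flow_amp * np.cos(2 * np.pi * (d - env.flow_peak_day) / 365))
    if env.flow_noise_cv > 0:
        flow = flow * np.exp(_ar1(rng, len(d), env.flow_noise_cv, 0.8))
    rate = env.freshet_rate_sep * np.exp(env.freshet_rate_trend * dy)
    if env.freshet_break_year is not None and year >= env.freshet_break_year:
        rate *= env.freshet_break_factor
    if rate > 0:
        autumn = (d >= 213) & (d <= 304)        # Aug 1 - Oct 31
        spikes = rng.random(len(d)) < np.where(autumn, rate, 0.0)
        sizes = rng.exponential(env.freshet_scale, size=len(d)) * spikes
        # each spike decays over ~3 days
        kernel = np.array([1.0, 0.6, 0.3])
        flow = flow + np.convolve(sizes, kernel)[:len(d)]
    flow = np.maximum(flow, 0.1)
    return (DailySeries(year, 1, flow), DailySeries(year, 1, temp))


def _ar1(rng: np.random.Generator, n: int, sd: float,
         rho: float) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho * rho), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def generate_timing_series(n_years: int, base: float, sigma: float,
                           break_index: int | None = None,
                           shift_per_year: float = 0.0,
                           level_shift: float = 0.0,
                           trend: float = 0.0,
                           seed: int = 0,
                           first_year: int = 1969) -> pd.Series:
    """A year-indexed median-timing series for trend/break recovery
    studies: an optional overall linear trend, plus (after the break) a
    step of ``level_shift`` days and an extra ``shift_per_year`` slope."""
    rng = np.random.default_rng(seed)
    years = np.arange(first_year, first_year + n_years)
    t = np.arange(n_years)
    signal = base + trend * t
    if break_index is not None:
        after = t > break_index
        signal = (signal + level_shift * after
                  + shift_per_year * np.maximum(0, t - break_index))
    return pd.Series(signal + rng.normal(0, sigma, n_years),
                     index=years, name="median_day")


@dataclass
class Dataset:
    """A full simulated study across years."""

    config: ScenarioConfig
    runs: dict[int, RunData]
    hatchery: dict[int, HatcheryData]
    environment: dict[int, tuple[DailySeries, DailySeries]]
    ground_truth: pd.DataFrame


def generate_dataset(config: ScenarioConfig) -> Dataset:
    runs, hatch, env, truth = {}, {}, {}, []
    for year in config.years:
        rd = generate_run(config, year)
        hd = generate_hatchery(config, year, rd.true_entries)
        runs[year], hatch[year] = rd, hd
        env[year] = generate_environment(config, year)
        w = rd.true_entries.values
        mean = float(np.average(rd.true_entries.days, weights=w))
        sd = float(np.sqrt(np.average((rd.true_entries.days - mean) ** 2,
                                      weights=w)))
        truth.append({
            "year": year,
            "true_entry_mean": mean,
            "true_entry_sd": sd,
            "true_h2": config.h2_true,
            "true_differential": hd.true_raw_differential,
        })
    return Dataset(config, runs, hatch, env, pd.DataFrame(truth))
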