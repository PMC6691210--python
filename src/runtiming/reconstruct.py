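"""River-entry reconstruction from sparse live-count surveys.

The pipeline is: linear interpolation of surveys to daily occupancy, an
accounting recursion converting occupancy to daily entries given a
stream-life schedule, and a cumulative-normal OLS fit that stabilizes the
oscillating raw entries into a smooth entry distribution. Spawning timing
is the entry distribution offset by the mean in-river delay before
spawning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .series import DailySeries, EntryDistribution, StreamLifeSchedule, TimingSummary

MIN_SURVEYS = 3
SIGMA_FLOOR = 0.5

DEFAULT_PERCENTILES = (10, 25, 50, 75, 90)


class YearExcludedError(ValueError):
    """Raised when a year has too few surveys to reconstruct reliably."""


@dataclass
class SurveyRecord:
    year: int
    day: int
    live_count: float


def interpolate_daily(surveys: list[SurveyRecord]) -> DailySeries:
    """Linearly interpolate survey counts to a daily occupancy series.

    The run is assumed absent outside the observed window: the series is
    padded with a zero on the day before the first survey and the day
    after the last.
    """
    if len(surveys) < MIN_SURVEYS:
        raise YearExcludedError(
            f"{len(surveys)} surveys; at least {MIN_SURVEYS} required")
    years = {s.year for s in surveys}
    if len(years) != 1:
        raise ValueError("surveys span multiple years")
    days = np.array([s.day for s in surveys], dtype=float)
    if not np.all(np.diff(days) > 0):
        raise ValueError("survey dates must be strictly increasing")
    counts = np.array([s.live_count for s in surveys], dtype=float)
    if np.any(counts < 0):
        raise ValueError("live counts must be non-negative")

    first = max(1, int(days[0]) - 1)
    last = min(366, int(days[-1]) + 1)
    xp = np.concatenate(([first], days, [last]))
    fp = np.concatenate(([0.0], counts, [0.0]))
    # guard against a survey on day 1 / day 366 duplicating the pad day
    keep = np.concatenate(([True], np.diff(xp) > 0))
    grid = np.arange(first, last + 1, dtype=float)
    daily = np.interp(grid, xp[keep], fp[keep])
    return DailySeries(surveys[0].year, first, daily)


def _anchors(live: DailySeries,
             schedule: StreamLifeSchedule) -> tuple[int, int]:
    if schedule.anchor_start_day is not None and schedule.anchor_end_day is not None:
        return schedule.anchor_start_day, schedule.anchor_end_day
    occupied = np.nonzero(live.values > 0)[0]
    if len(occupied) == 0:
        return live.first_day, live.last_day
    a0 = schedule.anchor_start_day
    a1 = schedule.anchor_end_day
    if a0 is None:
        a0 = live.first_day + int(occupied[0])
    if a1 is None:
        a1 = live.first_day + int(occupied[-1])
    return a0, a1


def reconstruct_entries(live: DailySeries,
                        schedule: StreamLifeSchedule) -> DailySeries:
    """Convert daily occupancy to daily entries via the deaths recursion.

    entering(t) = live(t) - live(t-1) + deaths(t), where deaths(t) are the
    entrants of the cohorts whose stream-life expires on day t; with a
    constant span L this is exactly deaths(t) = entering(t - L). Raw
    entries may be negative (observation and process error) — they are
    retained, and stabilized later by the cumulative-normal fit.
    """
    a0, a1 = _anchors(live, schedule)
    n = len(live.values)
    offsets = schedule.death_offset(live.days, a0, a1)
    dlive = np.diff(live.values, prepend=0.0)
    entries = np.zeros(n)
    pending = np.zeros(n + int(offsets.max()) + 1)
    for i in range(n):
        e = dlive[i] + pending[i]
        entries[i] = e
        pending[i + offsets[i]] += e
    return DailySeries(live.year, live.first_day, entries)


def _cdf_residuals(params: np.ndarray, days: np.ndarray,
                   cum: np.ndarray) -> np.ndarray:
    # C_t is entries through the END of day t, so the normal CDF is
    # evaluated at t + 0.5 (continuity correction for the daily grid)
    mu, sigma = params
    return stats.norm.cdf((days + 0.5 - mu) / sigma) - cum


def _first_exceed(cum: np.ndarray, q: float) -> int:
    """Index of the first element strictly above q (cum may oscillate)."""
    idx = int((cum > q).argmax())
    if cum[idx] <= q:
        idx = len(cum) - 1
    return idx


def _percentile_start(days: np.ndarray, cum: np.ndarray) -> tuple[float, float]:
    mu0 = float(days[_first_exceed(cum, 0.5)])
    d25 = float(days[_first_exceed(cum, 0.25)])
    d75 = float(days[_first_exceed(cum, 0.75)])
    sigma0 = max(SIGMA_FLOOR, (d75 - d25) / 1.349)
    return mu0, sigma0


def fit_entry_cdf(raw_entries: DailySeries, n_restarts: int = 3,
                  seed: int = 0) -> tuple[float, float, float]:
    """OLS fit of a normal CDF to the cumulative proportion of entries.

    Minimizes sum_t (Phi((t-mu)/sigma) - C_t)^2 where C_t is the running
    sum of raw entries divided by the total. Returns (mu, sigma, sse).
    """
    total = raw_entries.total
    if total <= 0:
        raise ValueError("total entries must be positive to fit a CDF")
    days = raw_entries.days.astype(float)
    cum = np.cumsum(raw_entries.values) / total
    mu0, sigma0 = _percentile_start(days, cum)

    lo = (days[0] - 60.0, SIGMA_FLOOR)
    hi = (days[-1] + 60.0, 200.0)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_restarts + 1):
        if k == 0:
            start = (mu0, sigma0)
        else:
            start = (float(np.clip(mu0 + rng.normal(0, 5), *[lo[0], hi[0]])),
                     float(np.clip(sigma0 * np.exp(rng.normal(0, 0.5)),
                                   lo[1], hi[1])))
        res = optimize.least_squares(_cdf_residuals, start, bounds=(lo, hi),
                                     args=(days, cum))
        sse = float(2 * res.cost)
        if best is None or sse < best[2]:
            best = (float(res.x[0]), float(res.x[1]), sse)
        if res.success and k == 0:
            break
    mu, sigma, sse = best
    return mu, sigma, sse


def fit_entry_cdf_batch(days: np.ndarray, cum: np.ndarray,
                        max_iter: int = 60,
                        tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized damped Gauss-Newton fit of normal CDFs to many
    cumulative-proportion curves at once (same OLS objective as
    :func:`fit_entry_cdf`).

    ``cum`` has shape (m, n_days); returns (mu, sigma) arrays of length m.
    Used by the Monte Carlo engine where one fit per draw and year is
    needed; agrees with the scalar path to ~1e-6.
    """
    cum = np.atleast_2d(cum)
    m = cum.shape[0]
    days = np.asarray(days, dtype=float)

    # percentile-based starts, per row
    idx50 = np.clip((cum > 0.5).argmax(axis=1), 0, len(days) - 1)
    idx25 = np.clip((cum > 0.25).argmax(axis=1), 0, len(days) - 1)
    idx75 = np.clip((cum > 0.75).argmax(axis=1), 0, len(days) - 1)
    mu = days[idx50].astype(float)
    sigma = np.maximum(SIGMA_FLOOR, (days[idx75] - days[idx25]) / 1.349)

    lam = np.full(m, 1e-3)
    days = days + 0.5   # same continuity correction as the scalar path
    z = (days[None, :] - mu[:, None]) / sigma[:, None]
    r = stats.norm.cdf(z) - cum
    sse = (r * r).sum(axis=1)
    for it in range(max_iter):
        phi = stats.norm.pdf(z)
        j_mu = -phi / sigma[:, None]
        j_sg = -phi * z / sigma[:, None]
        a11 = (j_mu * j_mu).sum(axis=1)
        a12 = (j_mu * j_sg).sum(axis=1)
        a22 = (j_sg * j_sg).sum(axis=1)
        g1 = (j_mu * r).sum(axis=1)
        g2 = (j_sg * r).sum(axis=1)
        # Levenberg damping on the normal equations
        d11 = a11 * (1 + lam) + 1e-12
        d22 = a22 * (1 + lam) + 1e-12
        det = d11 * d22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step_mu = -(d22 * g1 - a12 * g2) / det
        step_sg = -(-a12 * g1 + d11 * g2) / det
        mu_new = mu + step_mu
        sigma_new = np.maximum(SIGMA_FLOOR, sigma + step_sg)
        z_new = (days[None, :] - mu_new[:, None]) / sigma_new[:, None]
        r_new = stats.norm.cdf(z_new) - cum
        sse_new = (r_new * r_new).sum(axis=1)
        improved = sse_new <= sse
        mu = np.where(improved, mu_new, mu)
        sigma = np.where(improved, sigma_new, sigma)
        z = np.where(improved[:, None], z_new, z)
        r = np.where(improved[:, None], r_new, r)
        moved = np.abs(np.where(improved, sse - sse_new, 0.0))
        sse = np.where(improved, sse_new, sse)
        lam = np.where(improved, lam * 0.3, lam * 10.0)
        lam = np.clip(lam, 1e-9, 1e6)
        if it >= 3 and np.all(moved < tol):
            break
    return mu, sigma


def fit_entry_distribution(raw_entries: DailySeries,
                           spawn_delay: float = 0.0) -> EntryDistribution:
    mu, sigma, sse = fit_entry_cdf(raw_entries)
    return EntryDistribution(raw_entries.year, mu, sigma, sse,
                             raw_entries=raw_entries, spawn_delay=spawn_delay)


def spawning_distribution(entry: EntryDistribution,
                          delay: float) -> EntryDistribution:
    """Entry distribution offset by the mean days in-river before
    completing spawning; the spread is unchanged."""
    if not 0 <= delay <= 30:
        raise ValueError("spawning delay must be in [0, 30] days")
    return EntryDistribution(entry.year, entry.mu + delay, entry.sigma,
                             entry.fit_sse, raw_entries=entry.raw_entries,
                             spawn_delay=0.0)


def timing_percentiles(daily: DailySeries,
                       percentiles: tuple[int, ...] = DEFAULT_PERCENTILES,
                       label: str = "") -> TimingSummary:
    """Completion dates: for each p, the first day on which the cumulative
    proportion strictly exceeds p/100."""
    total = daily.total
    if total <= 0:
        raise ValueError("total must be positive for completion percentiles")
    cum = np.cumsum(daily.values) / total
    days = daily.days
    dates = {}
    for p in percentiles:
        idx = int((cum > p / 100.0).argmax())
        if cum[idx] <= p / 100.0:  # never exceeded (p == 100 edge)
            idx = len(days) - 1
        dates[p] = float(days[idx])
    return TimingSummary(daily.year, label, dates)


def percentiles_from_normal(mu: float, sigma: float,
                            percentiles: tuple[int, ...] = DEFAULT_PERCENTILES,
                            year: int = 0, label: str = "") -> TimingSummary:
    """Percentile dates of a fitted normal timing distribution."""
    dates = {p: float(mu + stats.norm.ppf(p / 100.0) * sigma)
             for p in percentiles}
    return TimingSummary(year, label, dates)
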