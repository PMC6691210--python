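"""Hatchery selection on spawn timing and its evolutionary response.

For each brood year the raw selection differential is the difference
between the mean hatchery spawn date and the whole-population mean (the
hatchery and natural means weighted by the share of the return spawned in
each setting). Because eggs fertilized in the hatchery survive to fry at
a far higher rate than eggs in the river, the raw differential is
weighted by the proportional survival advantage to give the effective
differential S; the breeder's equation ΔZ = h²·S then gives the expected
per-generation shift, and the mean ΔZ times the number of selected
generations gives the cumulative change. A Monte Carlo layer propagates
uniform parameter uncertainty (stream-life, spawning delay, survival
advantage) through the entire reconstruction-and-selection chain.

Sign convention: dates are day-of-year; negative differentials and
changes mean selection for earlier spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reconstruct import fit_entry_cdf_batch
from .series import DailySeries

TABLE_RANGES: dict[str, tuple[float, float]] = {
    # broad uniform ranges for the sensitivity analysis
    "initial": (14.0, 22.0),        # initial stream-life, days
    "final_frac": (0.5, 1.0),       # final stream-life as fraction of initial
    "trend": (-4.0, 0.0),           # total between-year change, days
    "delay": (5.0, 11.0),           # river entry to spawning, days
    "advantage": (0.6, 0.95),       # hatchery egg-to-fry survival advantage
}

POINT_ESTIMATES: dict[str, float] = {
    "initial": 18.0,
    "final_frac": 11.0 / 18.0,
    "trend": -2.0,
    "delay": 8.0,
    "advantage": 0.83,
}

H2_LEVELS = (0.3, 0.5, 0.83)
DEFAULT_GENERATION_TIME = 4


def survival_advantage(s_hatchery: float, s_natural: float) -> float:
    """(hatchery − natural) / hatchery egg-to-fry survival, in [0, 1)."""
    if not 0 < s_hatchery <= 1:
        raise ValueError("hatchery survival must be in (0, 1]")
    if not 0 <= s_natural <= s_hatchery:
        raise ValueError("natural survival must be in [0, hatchery survival]")
    return (s_hatchery - s_natural) / s_hatchery


def selection_differential(hatchery_mean: float, natural_mean: float,
                           p_hatchery: float,
                           advantage: float) -> tuple[float, float]:
    """Raw and survival-weighted selection differentials, in days.

    raw = hatchery mean − population mean, the population mean being the
    hatchery and natural means weighted by the proportion spawned in each
    setting; S = raw × advantage. Negative = selection for earlier.
    """
    if not 0 <= p_hatchery <= 1:
        raise ValueError("p_hatchery must be in [0, 1]")
    pop_mean = p_hatchery * hatchery_mean + (1 - p_hatchery) * natural_mean
    raw = hatchery_mean - pop_mean
    return raw, raw * advantage


def breeders_equation(h2: float, S: float) -> float:
    """Expected one-generation change ΔZ = h²·S, days per generation."""
    if not 0 <= h2 <= 1.2:
        raise ValueError("h2 outside the plausible range [0, 1.2]")
    if not np.isfinite(S):
        raise ValueError("selection differential must be finite")
    return h2 * S


@dataclass
class SelectionRecord:
    brood_year: int
    hatchery_mean_date: float
    natural_mean_date: float
    p_hatchery: float
    raw_differential: float
    S: float
    delta_z: float


def cumulative_change(records: list[SelectionRecord],
                      last_observed_year: int,
                      generation_time: int = DEFAULT_GENERATION_TIME
                      ) -> tuple[float, list[int], float]:
    """Total expected change: mean ΔZ over realized brood years times the
    generation multiplier (realized years / generation time).

    A brood year is realized only if its offspring could have returned by
    the final observed year (brood + generation time <= last year).
    """
    realized = [r for r in records
                if r.brood_year + generation_time <= last_observed_year]
    if not realized:
        raise ValueError("no realized brood years before "
                         f"{last_observed_year - generation_time + 1}")
    multiplier = len(realized) / generation_time
    mean_dz = float(np.mean([r.delta_z for r in realized]))
    return mean_dz * multiplier, [r.brood_year for r in realized], multiplier


@dataclass
class SelectionDataset:
    """Inputs to the selection chain that do not vary across Monte Carlo
    draws: daily occupancy per year (reconstruction input), hatchery mean
    spawn dates, and the proportion of the return spawned in the
    hatchery."""

    live_by_year: dict[int, DailySeries]
    hatchery_mean: dict[int, float]
    p_hatchery: dict[int, float]
    last_observed_year: int

    @property
    def years(self) -> list[int]:
        return sorted(y for y in self.live_by_year
                      if y in self.hatchery_mean
                      and np.isfinite(self.hatchery_mean[y]))


def _natural_mu_spawn(dataset: SelectionDataset, initial: np.ndarray,
                      final: np.ndarray, trend: np.ndarray,
                      delay: np.ndarray) -> np.ndarray:
    """Natural mean spawn dates, shape (draws, years).

    Per draw and year: rebuild daily entries from occupancy under the
    drawn stream-life schedule (scatter-add deaths scheduling, vectorized
    over draws), fit the cumulative-normal entry distribution, and offset
    by the drawn spawning delay.
    """
    years = dataset.years
    y0, y1 = years[0], years[-1]
    D = len(initial)
    out = np.empty((D, len(years)))
    for j, year in enumerate(years):
        live = dataset.live_by_year[year]
        frac_y = (year - y0) / (y1 - y0) if y1 > y0 else 0.0
        ini_y = np.maximum(1.0, initial + trend * frac_y)
        fin_y = np.clip(final + trend * frac_y, 1.0, ini_y)

        occupied = np.nonzero(live.values > 0)[0]
        a0 = live.first_day + int(occupied[0])
        a1 = live.first_day + int(occupied[-1])
        days = live.days
        if a1 > a0:
            w = np.clip((days - a0) / (a1 - a0), 0.0, 1.0)
        else:
            w = np.zeros(len(days))
        span = ini_y[:, None] + (fin_y - ini_y)[:, None] * w[None, :]
        offsets = np.maximum(1, np.rint(span)).astype(int)   # (D, n)

        n = len(days)
        dlive = np.diff(live.values, prepend=0.0)
        entries = np.empty((D, n))
        pending = np.zeros((D, n + offsets.max() + 1))
        rows = np.arange(D)
        for i in range(n):
            e = dlive[i] + pending[:, i]
            entries[:, i] = e
            pending[rows, i + offsets[:, i]] += e

        total = entries.sum(axis=1)
        total = np.where(total > 0, total, np.nan)
        cum = np.cumsum(entries, axis=1) / total[:, None]
        mu, _ = fit_entry_cdf_batch(days.astype(float), cum)
        out[:, j] = mu + delay
    return out


def _selection_chain(dataset: SelectionDataset, params: dict[str, np.ndarray],
                     h2: float,
                     generation_time: int = DEFAULT_GENERATION_TIME
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the full chain for arrays of parameter draws.

    Returns (cumulative change per draw, raw differentials (D, Y),
    natural means (D, Y)).
    """
    years = dataset.years
    natural = _natural_mu_spawn(dataset, params["initial"], params["final"],
                                params["trend"], params["delay"])
    hatch = np.array([dataset.hatchery_mean[y] for y in years])
    p = np.array([dataset.p_hatchery[y] for y in years])
    raw = (1.0 - p)[None, :] * (hatch[None, :] - natural)
    S = raw * params["advantage"][:, None]
    delta_z = h2 * S
    realized = np.array([y + generation_time <= dataset.last_observed_year
                         for y in years])
    if not realized.any():
        raise ValueError("no realized brood years in dataset")
    multiplier = realized.sum() / generation_time
    cumulative = delta_z[:, realized].mean(axis=1) * multiplier
    return cumulative, raw, natural


@dataclass
class PointEstimate:
    records: list[SelectionRecord]
    cumulative: float
    multiplier: float
    h2: float


def point_estimate(dataset: SelectionDataset, h2: float,
                   params: dict[str, float] | None = None,
                   generation_time: int = DEFAULT_GENERATION_TIME
                   ) -> PointEstimate:
    """Deterministic pipeline value at fixed parameters (defaults: the
    point estimates). Runs the same engine as the Monte Carlo with a
    single degenerate draw."""
    p = dict(POINT_ESTIMATES)
    if params:
        p.update(params)
    arrays = {
        "initial": np.array([p["initial"]]),
        "final": np.array([p["final_frac"] * p["initial"]]),
        "trend": np.array([p["trend"]]),
        "delay": np.array([p["delay"]]),
        "advantage": np.array([p["advantage"]]),
    }
    cumulative, raw, natural = _selection_chain(dataset, arrays, h2,
                                                generation_time)
    years = dataset.years
    records = []
    for j, year in enumerate(years):
        r = float(raw[0, j])
        S = r * p["advantage"]
        records.append(SelectionRecord(
            brood_year=year,
            hatchery_mean_date=dataset.hatchery_mean[year],
            natural_mean_date=float(natural[0, j]),
            p_hatchery=dataset.p_hatchery[year],
            raw_differential=r,
            S=S,
            delta_z=breeders_equation(h2, S),
        ))
    realized = sum(1 for y in years
                   if y + generation_time <= dataset.last_observed_year)
    return PointEstimate(records, float(cumulative[0]),
                         realized / generation_time, h2)


@dataclass
class MonteCarloResult:
    h2: float
    draws: pd.DataFrame              # parameter draws + cumulative_days
    raw_by_year: pd.DataFrame        # per-draw raw differentials, one col/year
    summaries: dict[str, float] = field(default_factory=dict)
    sensitivity: dict[str, float] = field(default_factory=dict)

    @property
    def cumulative(self) -> np.ndarray:
        return self.draws["cumulative_days"].to_numpy()


def _draw_params(ranges: dict[str, tuple[float, float]], n_draws: int,
                 seed: int) -> dict[str, np.ndarray]:
    """Independent uniform draws; each parameter gets its own child
    stream, so extending n_draws leaves earlier draws unchanged."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(TABLE_RANGES))
    params = {}
    for child, name in zip(children, TABLE_RANGES):
        lo, hi = ranges[name]
        if lo > hi:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        rng = np.random.default_rng(child)
        u = rng.random(n_draws)
        params[name] = lo + (hi - lo) * u
    params["final"] = params.pop("final_frac") * params["initial"]
    return params


def _first_order_sensitivity(x: np.ndarray, y: np.ndarray,
                             bins: int = 20) -> float:
    """Share of output variance explained by one parameter: variance of
    binned conditional means over total variance."""
    if np.ptp(x) == 0 or y.var() == 0:
        return 0.0
    edges = np.quantile(x, np.linspace(0, 1, bins + 1))
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)
    means = np.array([y[idx == b].mean() for b in range(bins)
                      if (idx == b).any()])
    weights = np.array([(idx == b).mean() for b in range(bins)
                        if (idx == b).any()])
    grand = float((means * weights).sum())
    return float(((means - grand) ** 2 * weights).sum() / y.var())


def monte_carlo(dataset: SelectionDataset, h2: float,
                ranges: dict[str, tuple[float, float]] | None = None,
                n_draws: int = 10_000, seed: int = 0,
                generation_time: int = DEFAULT_GENERATION_TIME
                ) -> MonteCarloResult:
    """Propagate uniform parameter uncertainty through the full
    reconstruction-and-selection chain at a fixed heritability."""
    ranges = {**TABLE_RANGES, **(ranges or {})}
    params = _draw_params(ranges, n_draws, seed)
    cumulative, raw, _ = _selection_chain(dataset, params, h2,
                                          generation_time)
    draws = pd.DataFrame({
        "draw": np.arange(n_draws),
        "h2": h2,
        "initial_stream_life": params["initial"],
        "final_stream_life": params["final"],
        "stream_life_trend": params["trend"],
        "spawning_delay": params["delay"],
        "advantage": params["advantage"],
        "cumulative_days": cumulative,
    })
    q25, q50, q75 = np.percentile(cumulative, [25, 50, 75])
    summaries = {
        "median": float(q50),
        "iqr_lo": float(q25),
        "iqr_hi": float(q75),
        "prop_negative": float((cumulative < 0).mean()),
    }
    sens_cols = {
        "stream_life": params["initial"],
        "stream_life_trend": params["trend"],
        "spawning_delay": params["delay"],
        "advantage": params["advantage"],
    }
    sensitivity = {k: _first_order_sensitivity(v, cumulative)
                   for k, v in sens_cols.items()}
    raw_by_year = pd.DataFrame(raw, columns=[str(y) for y in dataset.years])
    return MonteCarloResult(h2, draws, raw_by_year, summaries, sensitivity)
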