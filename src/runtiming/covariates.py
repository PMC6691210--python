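"""Environmental covariates of run timing.

Builds the annual predictor table from daily temperature and discharge:
calendar-season temperature means and annual maxima (observations
averaged by month first), and three flow summaries — mean
September–November discharge, the count of early-season days above the
long-term 75th percentile, and the cumulative September flow increase
(sum of positive day-to-day differences).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import DailySeries

# non-leap calendar; day-of-year 1 = Jan 1
_MONTH_LEN = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_END = np.cumsum(_MONTH_LEN)            # day-of-year of each month end
_MONTH_START = _MONTH_END - _MONTH_LEN + 1

SEASONS = {"spring": (3, 4, 5), "summer": (6, 7, 8), "autumn": (9, 10, 11)}

AUG1 = int(_MONTH_START[7])       # 213
SEP1 = int(_MONTH_START[8])       # 244
SEP30 = int(_MONTH_END[8])        # 273
NOV30 = int(_MONTH_END[10])       # 334


def month_of_day(day: np.ndarray | int) -> np.ndarray:
    """1-based month for a 1-based day-of-year (non-leap)."""
    return np.searchsorted(_MONTH_END, np.asarray(day)) + 1


def monthly_means(obs: DailySeries | pd.DataFrame,
                  value_col: str = "value") -> pd.Series:
    """Average observations within each month (sub-monthly records are
    collapsed to one value per month before any seasonal statistics)."""
    if isinstance(obs, DailySeries):
        df = pd.DataFrame({"month": month_of_day(obs.days),
                           value_col: obs.values})
    else:
        df = obs
        if "month" not in df.columns:
            df = df.assign(month=month_of_day(df["day"].to_numpy()))
    return df.groupby("month")[value_col].mean()


def seasonal_stats(obs: DailySeries | pd.DataFrame,
                   value_col: str = "value") -> dict[str, float]:
    """Season means (of monthly means) and the annual maximum.

    A season with no observations yields NaN, never zero.
    """
    monthly = monthly_means(obs, value_col)
    out: dict[str, float] = {}
    for season, months in SEASONS.items():
        vals = monthly.reindex(months).dropna()
        out[season] = float(vals.mean()) if len(vals) else float("nan")
    out["annual_max"] = float(monthly.max()) if len(monthly) else float("nan")
    return out


def _require_coverage(flow: DailySeries, first: int, last: int) -> None:
    missing = [d for d in (first, last) if not flow.first_day <= d <= flow.last_day]
    if missing or flow.first_day > first or flow.last_day < last:
        raise ValueError(
            f"flow series must cover days {first}-{last}; have "
            f"{flow.first_day}-{flow.last_day}")


def sep_nov_mean(flow: DailySeries) -> float:
    """Mean discharge over the months when most spawning occurs (Sep-Nov)."""
    _require_coverage(flow, SEP1, NOV30)
    sel = (flow.days >= SEP1) & (flow.days <= NOV30)
    return float(flow.values[sel].mean())


def high_flow_days(flow: DailySeries, threshold: float) -> int:
    """Days between Aug 1 and Sep 30 with discharge strictly above the
    long-term 75th percentile threshold."""
    _require_coverage(flow, AUG1, SEP30)
    sel = (flow.days >= AUG1) & (flow.days <= SEP30)
    return int((flow.values[sel] > threshold).sum())


def september_cum_increase(flow: DailySeries) -> float:
    """Cumulative September discharge increase: the sum of positive
    day-to-day differences within September."""
    _require_coverage(flow, SEP1, SEP30)
    sel = (flow.days >= SEP1) & (flow.days <= SEP30)
    q = flow.values[sel]
    return float(np.maximum(0.0, np.diff(q)).sum())


def long_term_p75(flows_by_year: dict[int, DailySeries]) -> float:
    """75th percentile of Aug 1 - Sep 30 discharge pooled over all years;
    the fixed reference for the high-flow day count."""
    vals = []
    for flow in flows_by_year.values():
        sel = (flow.days >= AUG1) & (flow.days <= SEP30)
        vals.append(flow.values[sel])
    return float(np.percentile(np.concatenate(vals), 75))


def flow_metrics(flow: DailySeries, threshold: float) -> dict[str, float]:
    return {
        "flow_sep_nov_mean": sep_nov_mean(flow),
        "flow_high_days": float(high_flow_days(flow, threshold)),
        "flow_sep_increase": september_cum_increase(flow),
    }


def build_covariate_table(
        env_by_year: dict[int, tuple[DailySeries, DailySeries]]
) -> pd.DataFrame:
    """Annual covariate table from {year: (discharge, temperature)}.

    ``ln_sep_increase`` is ln(cumulative September increase + 1), the
    +1 guarding years with monotone-declining September flow.
    """
    threshold = long_term_p75({y: f for y, (f, _) in env_by_year.items()})
    rows = []
    for year, (flow, temp) in sorted(env_by_year.items()):
        row: dict[str, float] = {"year": year}
        stats = seasonal_stats(temp)
        row.update({f"temp_{k}": v for k, v in stats.items()})
        row.update(flow_metrics(flow, threshold))
        row["ln_sep_increase"] = float(np.log1p(row["flow_sep_increase"]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")
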