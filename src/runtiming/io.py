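"""CSV schemas shared by the pipeline stages.

Every table has a header and stable column order; date-bearing tables
carry both an ISO 8601 date and a 1-based day_of_year column (the
day_of_year is authoritative for timing arithmetic).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .reconstruct import SurveyRecord
from .series import DailySeries

SCHEMAS: dict[str, list[str]] = {
    "surveys": ["year", "date", "day_of_year", "live_count"],
    "entries": ["year", "date", "day_of_year", "raw_entry"],
    "distributions": ["year", "mu_entry", "sigma", "mu_spawn", "fit_sse"],
    "timing_summary": ["year", "site", "d10", "d25", "d50", "d75", "d90",
                       "duration"],
    "env_daily": ["year", "date", "day_of_year", "discharge_cms", "temp_c"],
    "covariates": ["year", "covariate", "value"],
    "model_table": ["site", "model_id", "break_year", "aic", "delta_aic",
                    "weight", "n", "coefficients"],
    "correlations": ["metric_a", "metric_b", "r", "n"],
    "hatchery_eggs": ["year", "date", "day_of_year", "eggs", "females"],
    "otoliths": ["return_year", "spawn_date", "age", "parental_group"],
    "heritability": ["age_class", "h2", "ci_lo", "ci_hi", "r2", "n"],
    "selection_table": ["year", "hatchery_mean", "natural_mean", "p_hatchery",
                        "raw", "S", "delta_z"],
    "montecarlo": ["draw", "h2", "initial_stream_life", "final_stream_life",
                   "stream_life_trend", "spawning_delay", "advantage",
                   "cumulative_days"],
    "ground_truth": ["year", "true_entry_mean", "true_entry_sd", "true_h2",
                     "true_differential"],
}


class SchemaError(ValueError):
    """A CSV did not match its expected schema."""


def iso_date(year: int, day_of_year: int) -> str:
    return (_dt.date(int(year), 1, 1)
            + _dt.timedelta(days=int(day_of_year) - 1)).isoformat()


def checksum(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path | str, schema: str) -> Path:
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, index=False, float_format="%.6g")
    return path


def read_table(path: Path | str, schema: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema}: file not found: {path}")
    df = pd.read_csv(path)
    for i, col in enumerate(SCHEMAS[schema]):
        if col not in df.columns:
            raise SchemaError(
                f"{path}: column {i + 1} should be '{col}' (schema "
                f"'{schema}'); found {list(df.columns)}")
    return df


def _check_numeric(df: pd.DataFrame, path: Path | str, cols: list[str],
                   non_negative: tuple[str, ...] = ()) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(f"{path}: row {bad[0] + 2}, column '{col}': "
                              f"not numeric: {df.loc[bad[0], col]!r}")
        if col in non_negative and (vals.dropna() < 0).any():
            row = int(vals.index[(vals < 0).fillna(False)][0])
            raise SchemaError(f"{path}: row {row + 2}, column '{col}': "
                              "negative value")


def write_surveys(surveys: list[SurveyRecord], path: Path | str) -> Path:
    df = pd.DataFrame({
        "year": [s.year for s in surveys],
        "day_of_year": [s.day for s in surveys],
        "live_count": [s.live_count for s in surveys],
    })
    df["date"] = [iso_date(y, d) for y, d in zip(df.year, df.day_of_year)]
    return write_table(df, path, "surveys")


def read_surveys(path: Path | str) -> dict[int, list[SurveyRecord]]:
    df = read_table(path, "surveys")
    _check_numeric(df, path, ["year", "day_of_year", "live_count"],
                   non_negative=("live_count",))
    out: dict[int, list[SurveyRecord]] = {}
    for year, sub in df.groupby("year"):
        sub = sub.sort_values("day_of_year")
        out[int(year)] = [SurveyRecord(int(year), int(d), float(c))
                          for d, c in zip(sub.day_of_year, sub.live_count)]
    return out


def daily_series_frame(series_by_year: dict[int, DailySeries],
                       value_col: str) -> pd.DataFrame:
    rows = []
    for year, s in sorted(series_by_year.items()):
        for d, v in zip(s.days, s.values):
            rows.append({"year": year, "day_of_year": int(d),
                         "date": iso_date(year, int(d)), value_col: v})
    return pd.DataFrame(rows)


def frame_to_daily_series(df: pd.DataFrame,
                          value_col: str) -> dict[int, DailySeries]:
    out = {}
    for year, sub in df.groupby("year"):
        sub = sub.sort_values("day_of_year")
        days = sub["day_of_year"].to_numpy(int)
        if len(days) > 1 and not np.all(np.diff(days) == 1):
            gap = days[np.nonzero(np.diff(days) != 1)[0][0]]
            raise SchemaError(f"year {year}: day grid has a gap or "
                              f"duplicate after day {gap}")
        out[int(year)] = DailySeries(int(year), int(days[0]),
                                     sub[value_col].to_numpy(float))
    return out


def write_env_daily(env_by_year: dict[int, tuple[DailySeries, DailySeries]],
                    path: Path | str) -> Path:
    rows = []
    for year, (flow, temp) in sorted(env_by_year.items()):
        for d in flow.days:
            rows.append({"year": year, "day_of_year": int(d),
                         "date": iso_date(year, int(d)),
                         "discharge_cms": flow.value_on(int(d)),
                         "temp_c": temp.value_on(int(d))})
    return write_table(pd.DataFrame(rows), path, "env_daily")


def read_env_daily(path: Path | str
                   ) -> dict[int, tuple[DailySeries, DailySeries]]:
    df = read_table(path, "env_daily")
    _check_numeric(df, path, ["year", "day_of_year", "discharge_cms",
                              "temp_c"])
    flows = frame_to_daily_series(df, "discharge_cms")
    temps = frame_to_daily_series(df, "temp_c")
    return {y: (flows[y], temps[y]) for y in flows}


def write_hatchery_eggs(egg_take: dict[int, DailySeries],
                        females: dict[int, DailySeries],
                        path: Path | str) -> Path:
    rows = []
    for year, s in sorted(egg_take.items()):
        fem = females.get(year)
        for d, v in zip(s.days, s.values):
            rows.append({"year": year, "day_of_year": int(d),
                         "date": iso_date(year, int(d)), "eggs": v,
                         "females": fem.value_on(int(d)) if fem else np.nan})
    return write_table(pd.DataFrame(rows), path, "hatchery_eggs")


def read_hatchery_eggs(path: Path | str
                       ) -> tuple[dict[int, DailySeries],
                                  dict[int, DailySeries]]:
    df = read_table(path, "hatchery_eggs")
    _check_numeric(df, path, ["year", "day_of_year", "eggs", "females"],
                   non_negative=("eggs", "females"))
    return (frame_to_daily_series(df, "eggs"),
            frame_to_daily_series(df, "females"))
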