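"""Realized heritability of spawning date from thermal-mark groups.

Hatchery offspring carry otolith marks identifying whether their parents
were spawned early, middle, or late in the season. Regressing
standardized offspring group-mean spawn dates on standardized parental
group means, separately by age at return, gives the realized heritability
of spawn timing as the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .series import DailySeries

GROUPS = ("early", "middle", "late")


def standardize(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Scale to zero mean and unit variance.

    ``ddof=0`` uses the population-SD convention; the regression slope is
    identical under either convention provided both variables use the
    same one.
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot standardize a zero-variance sample")
    sd = x.std(ddof=ddof)
    return (x - x.mean()) / sd


def tercile_group_means(egg_take: DailySeries) -> dict[str, float]:
    """Egg-weighted mean spawn date of the early/middle/late thirds of a
    year's egg take — the resolution at which thermal marks identify
    parental timing."""
    if egg_take.total <= 0:
        return {}
    cum = np.cumsum(egg_take.values)
    tercile = (cum - 1e-9) // (cum[-1] / 3)
    means = {}
    for g, name in enumerate(GROUPS):
        w = egg_take.values[tercile == g]
        if w.sum() > 0:
            means[name] = float(np.average(egg_take.days[tercile == g],
                                           weights=w))
    return means


def build_parent_offspring_records(
        otoliths: pd.DataFrame,
        egg_take_by_year: dict[int, DailySeries]) -> pd.DataFrame:
    """Collapse otolith records to group × brood-year × age means.

    ``otoliths`` columns: return_year, spawn_date, age, parental_group.
    Parent group means are egg-weighted means from the brood year's egg
    take. Rows whose brood year lacks egg-take data are dropped.
    """
    df = otoliths.copy()
    df["brood_year"] = df["return_year"] - df["age"]
    group_means = {y: tercile_group_means(s)
                   for y, s in egg_take_by_year.items()}
    rows = []
    grouped = df.groupby(["brood_year", "parental_group", "age"])
    for (brood, group, age), sub in grouped:
        parents = group_means.get(int(brood), {})
        if group not in parents:
            continue
        rows.append({
            "brood_year": int(brood),
            "parental_group": group,
            "age_class": int(age),
            "parent_mean_date": parents[group],
            "offspring_mean_date": float(sub["spawn_date"].mean()),
            "n_offspring": int(len(sub)),
        })
    return pd.DataFrame(rows)


@dataclass
class HeritabilityEstimate:
    age_class: int
    h2: float
    ci95: tuple[float, float]
    se: float
    r2: float
    n_points: int

    def covers(self, value: float) -> bool:
        return self.ci95[0] <= value <= self.ci95[1]


def realized_h2(records: pd.DataFrame, age_class: int,
                weighted: bool = True, ddof: int = 0) -> HeritabilityEstimate:
    """Slope of standardized offspring means on standardized parent means.

    Both generations are standardized within the age class across all
    group-year points (pooled, preserving between-year signal). With
    ``weighted`` the regression weights each point by its offspring
    count; unweighted mode makes the slope exactly the Pearson r of the
    raw group means. The 95% CI uses the t distribution with n−2 df.
    """
    sub = records[records["age_class"] == age_class]
    if len(sub) < 3:
        raise ValueError(f"need >=3 group-year records for age {age_class}, "
                         f"have {len(sub)}")
    x = standardize(sub["parent_mean_date"].to_numpy(), ddof=ddof)
    y = standardize(sub["offspring_mean_date"].to_numpy(), ddof=ddof)
    w = sub["n_offspring"].to_numpy(float) if weighted else None
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)
    res = model.fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    n = len(sub)
    tcrit = float(stats.t.ppf(0.975, n - 2))
    return HeritabilityEstimate(
        age_class=age_class,
        h2=slope,
        ci95=(slope - tcrit * se, slope + tcrit * se),
        se=se,
        r2=float(res.rsquared),
        n_points=n,
    )


def heritability_table(records: pd.DataFrame,
                       weighted: bool = True) -> pd.DataFrame:
    rows = []
    for age in sorted(records["age_class"].unique()):
        est = realized_h2(records, int(age), weighted=weighted)
        rows.append({"age_class": est.age_class, "h2": est.h2,
                     "ci_lo": est.ci95[0], "ci_hi": est.ci95[1],
                     "r2": est.r2, "n": est.n_points})
    return pd.DataFrame(rows)
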