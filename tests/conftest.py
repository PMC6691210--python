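"""Shared fixtures: small scenarios and a session-scoped pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from runtiming.selection import SelectionDataset
from runtiming.series import DailySeries, StreamLifeSchedule
from runtiming.simulate import ScenarioConfig, forward_live_counts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A four-year scenario small enough for per-test simulation."""
    return ScenarioConfig(first_year=1991, last_year=1994, run_size=20_000,
                          otolith_samples_per_year=300, seed=7)


def make_normal_entries(year: int, mu: float, sd: float,
                        total: int = 5_000) -> DailySeries:
    """Deterministic (expected-count) daily entries from a normal curve."""
    from scipy.stats import norm
    lo = int(np.floor(mu - 5 * sd))
    hi = int(np.ceil(mu + 5 * sd))
    edges = np.arange(lo, hi + 2) - 0.5
    pmf = np.diff(norm.cdf(edges, loc=mu, scale=sd))
    return DailySeries(year, lo, total * pmf / pmf.sum())


@pytest.fixture
def tiny_selection_dataset():
    """Three brood years of noiseless occupancy with known hatchery means.

    The hatchery mean sits 5 days earlier than the entry mean + 8-day
    delay, so raw differentials are negative by construction.
    """
    schedule = StreamLifeSchedule(18.0, 11.0)
    live, hatch, p = {}, {}, {}
    for k, year in enumerate((2000, 2001, 2002)):
        entries = make_normal_entries(year, 270.0, 10.0)
        live[year] = forward_live_counts(entries, schedule)
        hatch[year] = 270.0 + 8.0 - 5.0
        p[year] = 0.1
    return SelectionDataset(live, hatch, p, last_observed_year=2006)
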