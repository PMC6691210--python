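"""Pipeline configuration and stage orchestration.

Each stage reads and writes the CSV schemas in :mod:`runtiming.io`, so
stages can be run standalone on intermediate files or chained end to end
(simulate → reconstruct → covariates → trends → heritability → selection
→ montecarlo → report).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import selection as sel
from .covariates import build_covariate_table
from .heritability import build_parent_offspring_records, heritability_table
from .reconstruct import (YearExcludedError, fit_entry_distribution,
                          interpolate_daily, reconstruct_entries,
                          spawning_distribution, timing_percentiles)
from .series import StreamLifeSchedule
from .simulate import ScenarioConfig, generate_dataset
from .trends import fit_suite, model_table, timing_correlations

log = logging.getLogger("runtiming")


@dataclass
class PipelineConfig:
    outdir: Path = Path("runtiming_out")
    site: str = "river"
    percentiles: tuple[int, ...] = (10, 25, 50, 75, 90)
    candidate_ids: list[str] | None = None      # None = all 16
    h2_levels: tuple[float, ...] = sel.H2_LEVELS
    mc_draws: int = 10_000
    generation_time: int = sel.DEFAULT_GENERATION_TIME
    selection_params: dict[str, float] = field(
        default_factory=lambda: dict(sel.POINT_ESTIMATES))
    s_hatchery: float | None = None   # optional: derive advantage from survivals
    s_natural: float | None = None
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.s_hatchery is not None or self.s_natural is not None:
            if self.s_hatchery is None or self.s_natural is None:
                raise ValueError("s_hatchery and s_natural must be set "
                                 "together")
            if self.s_natural > self.s_hatchery:
                raise ValueError(
                    "s_natural exceeds s_hatchery: the hatchery survival "
                    "advantage premise is violated")
            self.selection_params["advantage"] = sel.survival_advantage(
                self.s_hatchery, self.s_natural)
        for h2 in self.h2_levels:
            if not 0 <= h2 <= 1.2:
                raise ValueError(f"h2_levels entry {h2} outside [0, 1.2]")

    @property
    def data_dir(self) -> Path:
        return self.outdir / "data"

    @property
    def tables_dir(self) -> Path:
        return self.outdir / "tables"

    def schedule(self) -> StreamLifeSchedule:
        p = self.selection_params
        return StreamLifeSchedule(p["initial"], p["final_frac"] * p["initial"],
                                  p["trend"])

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = raw.pop("scenario", {})
        env = scenario.pop("env", {}) if isinstance(scenario, dict) else {}
        from .simulate import EnvConfig
        try:
            cfg = cls(**raw, scenario=ScenarioConfig(
                **scenario, env=EnvConfig(**env)))
        except TypeError as exc:
            raise ValueError(f"invalid configuration key: {exc}") from exc
        return cfg


def _log_input(path: Path) -> None:
    log.info("reading %s (sha256 %s)", path, rio.checksum(path))


def stage_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate the synthetic dataset and write its observable tables."""
    scen = dataclasses.replace(cfg.scenario, seed=cfg.seed)
    ds = generate_dataset(scen)
    d = cfg.data_dir
    d.mkdir(parents=True, exist_ok=True)
    surveys = [s for rd in ds.runs.values() for s in rd.surveys]
    paths = {
        "surveys": rio.write_surveys(surveys, d / "surveys.csv"),
        "hatchery_eggs": rio.write_hatchery_eggs(
            {y: h.egg_take for y, h in ds.hatchery.items()},
            {y: h.females_by_day for y, h in ds.hatchery.items()},
            d / "hatchery_eggs.csv"),
        "otoliths": rio.write_table(
            pd.concat([h.otoliths for h in ds.hatchery.values()],
                      ignore_index=True),
            d / "otoliths.csv", "otoliths"),
        "env_daily": rio.write_env_daily(ds.environment, d / "env_daily.csv"),
        "ground_truth": rio.write_table(ds.ground_truth,
                                        d / "ground_truth.csv",
                                        "ground_truth"),
    }
    # run sizes are observable (the whole return is counted at the locks)
    run_sizes = pd.DataFrame({
        "year": list(ds.runs),
        "run_size": [rd.true_entries.total for rd in ds.runs.values()]})
    run_sizes.to_csv(d / "run_sizes.csv", index=False)
    for p in paths.values():
        log.info("wrote %s (sha256 %s)", p, rio.checksum(p))
    return paths


def stage_reconstruct(cfg: PipelineConfig) -> dict[str, Path]:
    """Surveys → daily interpolation → entries → fitted distributions and
    timing percentiles."""
    src = cfg.data_dir / "surveys.csv"
    _log_input(src)
    surveys = rio.read_surveys(src)
    schedule = cfg.schedule()
    delay = cfg.selection_params["delay"]
    years = sorted(surveys)
    entries_by_year, dist_rows, summaries = {}, [], []
    for year in years:
        try:
            daily = interpolate_daily(surveys[year])
        except YearExcludedError as exc:
            log.warning("year %s excluded: %s", year, exc)
            continue
        sched = schedule.for_year(year, years[0], years[-1])
        raw = reconstruct_entries(daily, sched)
        entries_by_year[year] = raw
        entry = fit_entry_distribution(raw, spawn_delay=delay)
        spawn = spawning_distribution(entry, delay)
        dist_rows.append({"year": year, "mu_entry": entry.mu,
                          "sigma": entry.sigma, "mu_spawn": spawn.mu,
                          "fit_sse": entry.fit_sse})
        ts = timing_percentiles(daily, cfg.percentiles, label=cfg.site)
        summaries.append({"year": year, "site": cfg.site,
                          **{f"d{p}": ts.dates[p] for p in cfg.percentiles},
                          "duration": ts.duration})
    t = cfg.tables_dir
    entries_df = rio.daily_series_frame(entries_by_year, "raw_entry")
    paths = {
        "entries": rio.write_table(entries_df, t / "entries.csv", "entries"),
        "distributions": rio.write_table(pd.DataFrame(dist_rows),
                                         t / "distributions.csv",
                                         "distributions"),
        "timing_summary": rio.write_table(pd.DataFrame(summaries),
                                          t / "timing_summary.csv",
                                          "timing_summary"),
    }
    for p in paths.values():
        log.info("wrote %s", p)
    return paths


def stage_covariates(cfg: PipelineConfig) -> Path:
    src = cfg.data_dir / "env_daily.csv"
    _log_input(src)
    env = rio.read_env_daily(src)
    wide = build_covariate_table(env)
    long = (wide.reset_index().melt(id_vars="year", var_name="covariate",
                                    value_name="value"))
    path = rio.write_table(long, cfg.tables_dir / "covariates.csv",
                           "covariates")
    log.info("wrote %s", path)
    return path


def _covariate_frame(cfg: PipelineConfig) -> pd.DataFrame:
    long = rio.read_table(cfg.tables_dir / "covariates.csv", "covariates")
    wide = long.pivot(index="year", columns="covariate", values="value")
    # E1/E2 for river timing: log September flow increase; autumn temperature
    return pd.DataFrame({"E1": wide["ln_sep_increase"],
                         "E2": wide["temp_autumn"]})


def stage_trends(cfg: PipelineConfig) -> dict[str, Path]:
    """Candidate-model suite on median timing, plus cross-metric
    correlations."""
    summary = rio.read_table(cfg.tables_dir / "timing_summary.csv",
                             "timing_summary")
    timing = summary.set_index("year")["d50"]
    covars = _covariate_frame(cfg)
    fits = fit_suite(timing, covars, cfg.candidate_ids)
    table = model_table(fits)
    table.insert(0, "site", cfg.site)
    paths = {"model_table": rio.write_table(
        table, cfg.tables_dir / "model_table.csv", "model_table")}

    metrics = {f"{cfg.site}_{c}": summary.set_index("year")[c]
               for c in ("d10", "d50", "d90", "duration")}
    rmat = timing_correlations(metrics)
    rows = []
    names = list(rmat.columns)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = pd.concat([metrics[a], metrics[b]], axis=1,
                                join="inner").dropna()
            rows.append({"metric_a": a, "metric_b": b,
                         "r": rmat.loc[a, b], "n": len(overlap)})
    paths["correlations"] = rio.write_table(
        pd.DataFrame(rows), cfg.tables_dir / "correlations.csv",
        "correlations")
    for p in paths.values():
        log.info("wrote %s", p)
    return paths


def stage_heritability(cfg: PipelineConfig) -> Path:
    oto_path = cfg.data_dir / "otoliths.csv"
    egg_path = cfg.data_dir / "hatchery_eggs.csv"
    _log_input(oto_path)
    _log_input(egg_path)
    otoliths = rio.read_table(oto_path, "otoliths")
    egg_take, _ = rio.read_hatchery_eggs(egg_path)
    records = build_parent_offspring_records(otoliths, egg_take)
    table = heritability_table(records)
    path = rio.write_table(table, cfg.tables_dir / "heritability.csv",
                           "heritability")
    log.info("wrote %s", path)
    return path


def build_selection_dataset(cfg: PipelineConfig) -> sel.SelectionDataset:
    surveys = rio.read_surveys(cfg.data_dir / "surveys.csv")
    egg_take, females = rio.read_hatchery_eggs(
        cfg.data_dir / "hatchery_eggs.csv")
    run_sizes = pd.read_csv(cfg.data_dir / "run_sizes.csv").set_index("year")

    live, hatch_mean, p_hatch = {}, {}, {}
    for year in sorted(surveys):
        try:
            live[year] = interpolate_daily(surveys[year])
        except YearExcludedError:
            continue
        eggs = egg_take.get(year)
        if eggs is None or eggs.total <= 0:
            continue
        hatch_mean[year] = float(np.average(eggs.days, weights=eggs.values))
        trapped = 2.0 * females[year].total
        total = float(run_sizes.loc[year, "run_size"])
        p_hatch[year] = float(np.clip(trapped / total, 0.0, 1.0))
    last = max(surveys)
    return sel.SelectionDataset(live, hatch_mean, p_hatch, last)


def stage_selection(cfg: PipelineConfig) -> Path:
    """Deterministic selection chain at the point estimates, at the middle
    heritability level."""
    ds = build_selection_dataset(cfg)
    h2 = cfg.h2_levels[len(cfg.h2_levels) // 2]
    pe = sel.point_estimate(ds, h2, cfg.selection_params,
                            cfg.generation_time)
    rows = [{"year": r.brood_year, "hatchery_mean": r.hatchery_mean_date,
             "natural_mean": r.natural_mean_date,
             "p_hatchery": r.p_hatchery, "raw": r.raw_differential,
             "S": r.S, "delta_z": r.delta_z} for r in pe.records]
    path = rio.write_table(pd.DataFrame(rows),
                           cfg.tables_dir / "selection_table.csv",
                           "selection_table")
    log.info("point-estimate cumulative change (h2=%s): %.2f days "
             "(multiplier %.2f)", h2, pe.cumulative, pe.multiplier)
    log.info("wrote %s", path)
    return path


def stage_montecarlo(cfg: PipelineConfig) -> Path:
    ds = build_selection_dataset(cfg)
    frames = []
    for h2 in cfg.h2_levels:
        mc = sel.monte_carlo(ds, h2, n_draws=cfg.mc_draws, seed=cfg.seed,
                             generation_time=cfg.generation_time)
        frames.append(mc.draws)
        log.info("h2=%.2f: median %.1f d, IQR [%.1f, %.1f], P(<0)=%.3f",
                 h2, mc.summaries["median"], mc.summaries["iqr_lo"],
                 mc.summaries["iqr_hi"], mc.summaries["prop_negative"])
    path = rio.write_table(pd.concat(frames, ignore_index=True),
                           cfg.tables_dir / "montecarlo.csv", "montecarlo")
    log.info("wrote %s", path)
    return path


def stage_report(cfg: PipelineConfig) -> Path:
    """Assemble a plain-text/markdown report plus vector figures."""
    from . import report as _report
    return _report.build_report(cfg)


STAGES = {
    "simulate": stage_simulate,
    "reconstruct": stage_reconstruct,
    "covariates": stage_covariates,
    "trends": stage_trends,
    "heritability": stage_heritability,
    "selection": stage_selection,
    "montecarlo": stage_montecarlo,
    "report": stage_report,
}

PIPELINE_ORDER = list(STAGES)


def run_pipeline(cfg: PipelineConfig, simulate: bool = True) -> Path:
    """Run every stage in order; returns the report path."""
    for name in PIPELINE_ORDER:
        if name == "simulate" and not simulate:
            continue
        log.info("=== stage: %s ===", name)
        STAGES[name](cfg)
    return cfg.outdir / "report.md"
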