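"""Report assembly: summary markdown plus vector figures."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import io as rio
from . import selection as sel
from .pipeline import PipelineConfig, build_selection_dataset

log = logging.getLogger("runtiming")


def _fig_timing(cfg: PipelineConfig, figdir: Path) -> Path:
    summary = rio.read_table(cfg.tables_dir / "timing_summary.csv",
                             "timing_summary")
    fits = rio.read_table(cfg.tables_dir / "model_table.csv", "model_table")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(summary["year"], summary["d50"], "o", mfc="none", color="k",
            label="median date")
    ax.fill_between(summary["year"], summary["d10"], summary["d90"],
                    alpha=0.15, color="steelblue", label="10–90%")
    best = fits.iloc[0]
    if pd.notna(best["break_year"]):
        ax.axvline(best["break_year"], ls="--", color="grey",
                   label=f"break {int(best['break_year'])}")
    ax.set_xlabel("year")
    ax.set_ylabel("day of year")
    ax.set_title(f"{cfg.site}: run timing (best model "
                 f"{best['model_id']}, weight {best['weight']:.2f})")
    ax.legend(frameon=False, fontsize=8)
    path = figdir / "timing_trend.svg"
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def _fig_selection(cfg: PipelineConfig, figdir: Path) -> Path:
    ds = build_selection_dataset(cfg)
    h2 = cfg.h2_levels[len(cfg.h2_levels) // 2]
    mc = sel.monte_carlo(ds, h2, n_draws=min(cfg.mc_draws, 2000),
                         seed=cfg.seed, generation_time=cfg.generation_time)
    fig, ax = plt.subplots(figsize=(8, 4))
    data = [mc.raw_by_year[c].to_numpy() for c in mc.raw_by_year.columns]
    ax.boxplot(data, tick_labels=mc.raw_by_year.columns, showfliers=False)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_ylabel("raw selection differential (days)")
    ax.set_xlabel("brood year")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    path = figdir / "selection_differentials.svg"
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def _fig_montecarlo(cfg: PipelineConfig, figdir: Path) -> Path:
    mc = rio.read_table(cfg.tables_dir / "montecarlo.csv", "montecarlo")
    fig, axes = plt.subplots(1, len(cfg.h2_levels), figsize=(10, 3),
                             sharex=True)
    if len(cfg.h2_levels) == 1:
        axes = [axes]
    for ax, h2 in zip(axes, cfg.h2_levels):
        vals = mc.loc[mc["h2"] == h2, "cumulative_days"]
        ax.hist(vals, bins=40, color="steelblue")
        ax.axvline(0, ls="--", color="k", lw=0.8)
        ax.set_title(f"h² = {h2}")
        ax.set_xlabel("cumulative change (days)")
    path = figdir / "montecarlo_hist.svg"
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def build_report(cfg: PipelineConfig) -> Path:
    figdir = cfg.outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    figs = [_fig_timing(cfg, figdir), _fig_selection(cfg, figdir),
            _fig_montecarlo(cfg, figdir)]

    fits = rio.read_table(cfg.tables_dir / "model_table.csv", "model_table")
    herit = rio.read_table(cfg.tables_dir / "heritability.csv",
                           "heritability")
    seltab = rio.read_table(cfg.tables_dir / "selection_table.csv",
                            "selection_table")
    mc = rio.read_table(cfg.tables_dir / "montecarlo.csv", "montecarlo")

    lines = [f"# Run-timing report: {cfg.site}", ""]
    best = fits.iloc[0]
    lines += ["## Trend model selection",
              f"Best model: **{best['model_id']}** "
              f"(AIC {best['aic']:.2f}, weight {best['weight']:.2f}, "
              f"break year {best['break_year']})", "",
              fits.head(5).to_markdown(index=False), ""]
    lines += ["## Realized heritability of spawn timing", "",
              herit.to_markdown(index=False), ""]
    mean_raw = seltab["raw"].mean()
    mean_s = seltab["S"].mean()
    lines += ["## Hatchery selection on spawn timing",
              f"Mean raw differential: {mean_raw:.2f} days; "
              f"mean survival-weighted differential S: {mean_s:.2f} days.",
              ""]
    lines += ["## Monte Carlo cumulative change", ""]
    for h2 in cfg.h2_levels:
        vals = mc.loc[mc["h2"] == h2, "cumulative_days"]
        lines.append(f"- h² = {h2}: median {vals.median():.1f} days, "
                     f"IQR [{vals.quantile(0.25):.1f}, "
                     f"{vals.quantile(0.75):.1f}], "
                     f"P(earlier) = {(vals < 0).mean():.3f}")
    lines += ["", "## Figures",
              *[f"- {p.relative_to(cfg.outdir)}" for p in figs], ""]
    path = cfg.outdir / "report.md"
    path.write_text("\n".join(lines))
    log.info("wrote %s", path)
    return path
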