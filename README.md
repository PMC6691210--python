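# runtiming

Reconstruction and evolutionary analysis of sockeye salmon run timing
from sparse spawning-ground surveys.

Adult sockeye enter their natal river over a few autumn weeks, hold for
one to three weeks, spawn, and die. Agencies rarely observe entries
directly; they count *live fish on the spawning grounds* every several
days. `runtiming` turns those sparse live counts into river-entry and
spawning-date distributions, tests whether timing has shifted over
decades (and whether environmental covariates or a regime break explain
the shift), estimates the realized heritability of spawn date from
thermally marked hatchery offspring, and quantifies the expected
evolutionary response to hatchery broodstock selection with a Monte
Carlo uncertainty layer.

## What the package computes

1. **Run-timing reconstruction** (`runtiming.reconstruct`). Linear
   interpolation of surveys to daily occupancy; a deaths/entries
   accounting recursion (`entering(t) = live(t) − live(t−1) + deaths(t)`,
   deaths scheduled per entry cohort under a stream-life schedule that
   declines within and between seasons); and a cumulative-normal
   least-squares fit that stabilizes the oscillating raw entries into a
   smooth entry distribution. Spawning timing is the entry distribution
   offset by the mean in-river delay.
2. **Environmental covariates** (`runtiming.covariates`). Calendar-season
   temperature means (observations averaged by month first), mean
   September–November discharge, days above the long-term 75th-percentile
   flow, and the cumulative September flow increase (sum of positive
   day-to-day rises — a freshet index).
3. **Trend attribution** (`runtiming.trends`). Sixteen Gaussian linear
   candidates for median timing — stationary, covariate, linear-trend,
   and regime-break families with full break interactions — compared by
   AIC and Akaike weights, with exhaustive break-year search.
4. **Realized heritability** (`runtiming.heritability`). Otolith-marked
   offspring are traced to early/middle/late parental egg-take terciles;
   the slope of standardized offspring group-mean spawn dates on
   standardized parental means, by age at return, is the realized h².
5. **Selection response** (`runtiming.selection`). Because hatchery
   egg-to-fry survival (~0.93) far exceeds in-river survival (~0.17),
   spawn dates favored by the hatchery weir are selected. The raw
   hatchery-minus-population differential is weighted by the survival
   advantage to give S; the breeder's equation ΔZ = h²·S gives the
   per-generation shift; cumulative change multiplies the mean ΔZ by the
   number of realized brood years per generation. A vectorized Monte
   Carlo propagates uniform uncertainty in stream-life, spawning delay,
   and survival advantage through the *entire* reconstruction-and-
   selection chain.
6. **Synthetic data** (`runtiming.simulate`). A generator whose defaults
   encode the reference study conditions (1991–2015 returns, ~250,000
   fish pre-2007, stream-life 18→11 days declining 2 days across the
   period, 8-day spawning delay, a weir window that misses the latest
   ~40% of the run, 14% of the return trapped) with known ground truth
   for every estimator in the package.

## Worked example

```python
import numpy as np

from runtiming.reconstruct import (SurveyRecord, fit_entry_distribution,
                                   interpolate_daily, reconstruct_entries,
                                   spawning_distribution)
from runtiming.selection import (breeders_equation, selection_differential,
                                 survival_advantage)
from runtiming.series import StreamLifeSchedule

# Live counts from six surveys of one season (day-of-year, count)
surveys = [SurveyRecord(2003, d, c) for d, c in
           [(248, 310.0), (255, 2140.0), (262, 3500.0),
            (269, 2970.0), (276, 1130.0), (283, 220.0)]]

daily = interpolate_daily(surveys)                    # daily occupancy
schedule = StreamLifeSchedule(initial=18, final=11)   # days alive in-river
entries = reconstruct_entries(daily, schedule)        # deaths/entries recursion
entry = fit_entry_distribution(entries)               # cumulative-normal fit
spawn = spawning_distribution(entry, delay=8)

print(f"total entries {entries.total:,.0f}, "
      f"entry mean day {entry.mu:.1f} (sd {entry.sigma:.1f}), "
      f"spawn mean day {spawn.mu:.1f}")

# Selection arithmetic at the published point values
adv = survival_advantage(s_hatchery=0.93, s_natural=0.17)
raw, S = selection_differential(hatchery_mean=spawn.mu - 4.7,
                                natural_mean=spawn.mu,
                                p_hatchery=0.17, advantage=0.83)
print(f"advantage {adv:.2f}, raw differential {raw:.1f} d, "
      f"S {S:.1f} d, dZ(h2=0.5) {breeders_equation(0.5, S):.1f} d/generation")
```

Output:

```
total entries 4,323, entry mean day 256.5 (sd 7.5), spawn mean day 264.5
advantage 0.82, raw differential -3.9 d, S -3.2 d, dZ(h2=0.5) -1.6 d/generation
```

## Command-line pipeline

Each analysis stage is a subcommand that reads and writes CSVs under one
output directory, so stages can run standalone on intermediate files or
chained end to end:

```bash
runtiming all --outdir demo --seed 1 --mc-draws 2000 -v
```

```
INFO runtiming: === stage: heritability ===
INFO runtiming: wrote demo/tables/heritability.csv
INFO runtiming: === stage: selection ===
INFO runtiming: point-estimate cumulative change (h2=0.5): -10.69 days (multiplier 5.25)
INFO runtiming: === stage: montecarlo ===
INFO runtiming: h2=0.30: median -5.2 d, IQR [-7.0, -3.4], P(<0)=0.991
INFO runtiming: h2=0.50: median -8.7 d, IQR [-11.7, -5.7], P(<0)=0.991
INFO runtiming: h2=0.83: median -14.4 d, IQR [-19.5, -9.5], P(<0)=0.991
```

With the defaults the recovered heritability table (truth: h² = 0.8)
reads:

```
age_class      h2    ci_lo    ci_hi      r2   n
        4  0.8063   0.6633   0.9493  0.6337  75
        5  0.7786   0.6314   0.9258  0.6035  75
```

Outputs under `--outdir`: `data/` (simulated surveys, egg takes, otolith
marks, daily environment, ground truth), `tables/` (entries, fitted
distributions, timing percentiles, covariates, the 16-model AIC table,
correlations, heritability, selection, Monte Carlo draws), `figures/`
(SVG), and `report.md`. Run `runtiming --help` for the stage list and
`runtiming all --no-simulate` to analyze existing data files laid out in
the same schemas (`runtiming.io.SCHEMAS`).

A YAML file (`--config`) controls every scenario and analysis parameter;
command-line flags `--outdir/--seed/--mc-draws` override it.

## Documentation

`docs/methods.md` describes the statistical model behind each stage, all
parameters with units and defaults, the scope of the synthetic
generator, and numerical choices and limitations.
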