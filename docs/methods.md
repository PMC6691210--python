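# Methods

All timing arithmetic uses 1-based day-of-year on a non-leap calendar
(Jan 1 = day 1, Aug 1 = 213, Sep 1 = 244, Sep 30 = 273, Nov 30 = 334); a
season never wraps a year boundary. Negative differentials and changes
always mean *earlier* spawning.

## 1. Run-timing reconstruction

**Inputs.** Per year: live-count surveys `(day, count)` taken every few
days, and a stream-life schedule.

**Stream-life schedule.** `StreamLifeSchedule(initial, final,
between_year_trend)` gives the days an adult survives in-river as a
linear function of entry date: `initial` days for the earliest entrants
declining to `final` for the latest (early fish hold longer before
spawning). `between_year_trend` is the *total* additive change in both
endpoints from the first to the last year of the dataset — not a
per-year rate — because plausible magnitudes (a few days over a
multi-decade study) would otherwise drive stream-life negative within a
few years. Per-cohort spans are clamped at 1 day. Within-year
interpolation anchors default to the extent of the observed run.

**Interpolation.** Surveys are linearly interpolated to a daily
occupancy series, padded with a zero the day before the first and after
the last survey (the run is assumed absent outside the observed window).
Years with fewer than 3 surveys are excluded.

**Deaths/entries recursion.** With `deaths(t)` the entrants of cohorts
whose stream-life expires on day `t`:

    entering(t) = live(t) − live(t−1) + deaths(t)

For a constant span `L` this reduces to `deaths(t) = entering(t−L)`;
with a date-dependent span, entrants on day `s` are scheduled to die on
day `s + max(1, round(span(s)))`. The recursion inverts the forward
cohort model exactly: for integer spans and exact occupancy it recovers
the entry series to machine precision. Observation noise makes raw
entries oscillate (including below zero); they are retained unmodified
and stabilized by the next step.

**Cumulative-normal fit.** The normal entry distribution `(μ, σ)`
minimizes the ordinary least-squares objective

    Σ_t [ Φ((t + 0.5 − μ)/σ) − C_t ]²

where `C_t` is the cumulative proportion of raw entries through day `t`.
The `+0.5` continuity correction accounts for `C_t` representing entries
through the *end* of day `t`; without it the fitted mean is biased ~half
a day early. Starting values come from the empirical 25th/50th/75th
crossing days (`σ₀ = (d75 − d25)/1.349`); the scalar path
(`scipy.optimize.least_squares`, bounded, 3 jittered restarts if the
first solve fails) and the vectorized batch path (damped Gauss–Newton on
the same objective, used by the Monte Carlo) agree to ~1e-6. `σ` is
floored at 0.5 day so point-mass years stay finite.

**Spawning timing.** The entry distribution shifted by the mean in-river
delay before spawning (bounded to 0–30 days); the spread is unchanged.
Completion percentiles of any daily series are reported as the first day
whose cumulative proportion strictly exceeds p/100.

## 2. Environmental covariates

Computed per year from daily discharge (m³/s) and water temperature
(°C):

- **Seasonal temperature**: observations are averaged within month
  first; a season mean (spring = Mar–May, summer = Jun–Aug, autumn =
  Sep–Nov) is the mean of its monthly means, and the annual maximum is
  the largest monthly mean. Seasons with no observations are NaN, never
  zero.
- **Sep–Nov mean discharge** over the spawning months.
- **High-flow days**: days between Aug 1 and Sep 30 strictly above the
  long-term 75th percentile of discharge, the percentile pooled over all
  years of the same window.
- **Cumulative September increase**: the sum of positive day-to-day
  discharge differences within September — a rainfall-freshet index.
  The model covariate is `ln(increase + 1)`.

## 3. Trend models

Median timing by year is modeled with 16 Gaussian linear candidates
crossing four structures {stationary (1), regime break (2), linear year
trend (3), break + trend (4)} with covariate subsets {none (a), E1 (b),
E2 (c), E1+E2 (d)}. The break indicator `R` is 0 before the break year
and 1 from it onward; break models interact every slope and covariate
with `R`, so each regime has its own coefficients. Here E1 =
`ln_sep_increase` and E2 = autumn temperature.

- **Estimation**: ordinary least squares on a z-scored design (unit
  variance covariates, centered year) for conditioning; reported
  coefficients are recovered on the original scale by projecting the
  fitted values onto the raw design, which is exact because both designs
  span the same column space.
- **AIC**: `2k − 2 lnL` with `k` = number of coefficients + 1 (the error
  variance is counted, matching R's `AIC` for `lm`);
  `lnL = −n/2·(ln(2π·RSS/n) + 1)`. Akaike weights are the normalized
  relative likelihoods `exp(−ΔAIC/2)`.
- **Break search**: exhaustive scan over feasible break years, ties to
  the earliest year. Each segment must hold one more observation than
  its per-segment coefficient count — 3 for the trend-only break model
  (a line plus a residual), more for the fully interacted covariate
  models; scan years whose design is nonetheless rank-deficient are
  skipped.
- **Identifiability caveat**: for a pure slope kink (no level shift) the
  break year is only weakly identified — neighboring break years can
  absorb the misfit in their free per-segment intercept and slope at a
  cost well under one AIC unit — so with realistic noise the break
  estimate carries a few years of spread even though the break *family*
  wins decisively. Step changes localize much more sharply.
- **Correlations** between timing metrics (d10/d50/d90/duration across
  sites) are pairwise-complete Pearson r, requiring ≥ 5 shared years and
  nonzero variance.

## 4. Realized heritability

Hatchery offspring carry otolith thermal marks identifying their
parents' egg-take tercile (early/middle/late third of the season's
cumulative egg take, each summarized by its egg-weighted mean spawn
date). Otolith records are collapsed to group × brood-year × age-class
means; the realized h² per age class is the slope of standardized
offspring means on standardized parental means, pooled across brood
years (preserving between-year signal).

Standardization uses the population-SD convention (`ddof=0`); the slope
is identical under either convention when both variables use the same
one. By default the regression weights each point by its offspring
count; unweighted, the slope is exactly the Pearson correlation of the
raw group means. The 95% CI is `slope ± t₀.₉₇₅(n−2)·SE`. Because both
axes are standardized, the slope estimates the parent–offspring
*correlation*; it equals h² when the offspring-generation variance
matches the parental one (see §6 on how the generator maintains this).

## 5. Selection differential and response

Per brood year, with hatchery mean spawn date `H`, natural-spawner mean
`N`, and proportion `p` of the return spawned in the hatchery:

    raw = H − [p·H + (1 − p)·N] = (1 − p)(H − N)
    S   = raw × advantage,  advantage = (s_hatchery − s_natural)/s_hatchery
    ΔZ  = h² · S                       (breeder's equation)

The natural mean is reconstructed from survey occupancy by §1 under the
stream-life and delay parameters; the hatchery mean is the egg-weighted
mean egg-take date. Cumulative change is the mean ΔZ over *realized*
brood years (brood + generation time ≤ last observed year) times the
generation multiplier (realized years / generation time, default 4-year
generation).

**Parameter uncertainty.** Broad uniform ranges (point values in
parentheses):

| parameter | range | point |
|---|---|---|
| initial stream-life (d) | 14–22 | 18 |
| final / initial ratio | 0.5–1.0 | 11/18 |
| stream-life trend, total days | −4–0 | −2 |
| spawning delay (d) | 5–11 | 8 |
| survival advantage | 0.60–0.95 | 0.83 |

`survival_advantage(0.93, 0.17)` evaluates to 0.8172; the tabulated
point value 0.83 reflects rounding in the published survivals and is
used where the table is the input. The Monte Carlo draws parameters
independently (each from its own `SeedSequence` child, so extending the
draw count leaves earlier draws unchanged) and pushes every draw through
the full reconstruction-and-selection chain, vectorized across draws:
scatter-add death scheduling for the recursion and the batch
Gauss–Newton CDF fit. The deterministic point estimate runs the same
engine with one degenerate draw, so collapsing the ranges to points
reproduces it exactly. Summaries: median, IQR, proportion of draws
negative; first-order sensitivity is the variance of 20-quantile-bin
conditional means over total variance.

## 6. Synthetic data generator

Scope: the generator produces every observable the analysis stages
consume — surveys, hatchery egg takes, otolith marks, daily environment
— with known ground truth, under the same structural assumptions the
estimators make (normal entry curve, cohort stream-life, binomial weir
trapping). It is a calibration and validation instrument, not a
population-dynamics model: no density dependence, fishery, straying, or
inter-population exchange.

Defaults encode the reference study conditions: returns 1991–2015 of
250,000 fish (75,000 from 2007), entry timing N(day 270, 10 d),
stream-life 18→11 days with −2 days total between-year trend, 8-day
spawning delay, surveys every ~4–10 days with lognormal CV 0.15 noise,
weir window days 245–273 (truncating the late ~40% of the run), 14% of
the return trapped, egg-to-fry survival 0.93 (hatchery) vs 0.17
(river), h²_true = 0.8, 1,200 otolith samples per brood year, 80%
age-4 returns. Mean fecundity is fixed at 3,200 eggs/female; only
relative egg-weighted quantities depend on it. Default entry timing is
stationary across years; shifting or regime-break scenarios are
configured via a per-year `entry_mean` mapping, or studied directly with
`generate_timing_series` (linear trend, level shift, and/or slope kink
plus i.i.d. noise).

Offspring spawn dates follow the infinitesimal-model shift: population
mean + h²·(parental-group deviation) + a group×age environmental
deviation + age and return-year effects + individual noise (SD 5 d).
The group-level deviation has SD `sd(parental deviations)·√(1 − h⁴)`,
which keeps the offspring-generation group-mean variance equal to the
parental one; without it the standardized parent–offspring slope would
estimate ~1 regardless of the true h² (§4).

Environment: temperature is a seasonal sinusoid plus linear warming and
AR(1) noise; discharge is a seasonal baseline with autocorrelated
multiplicative noise and exponential rainfall-freshet spikes
(Aug–Oct, 3-day decay) whose September frequency can trend or break
between years.

Randomness: every component (run, surveys, hatchery, otoliths,
environment, year effects) draws from
`default_rng([seed, year, component_id])`, so components are independent
and any year is reproducible in isolation.

## 7. Numerical choices

- Exhaustive break scan rather than a smoothed estimator: the series
  are short (tens of years), so the O(years × models) scan is cheap and
  exact; AIC ties break to the earliest year for determinism.
- The Monte Carlo vectorizes the per-draw recursion with a scatter-add
  over death days and fits all draws' CDFs simultaneously with a
  Levenberg-damped 2×2 Gauss–Newton; 10,000 draws across the full chain
  complete in well under a minute per heritability level. Batch and
  scalar fits agree to ~1e-6; batch convergence is joint across rows,
  so extending the draw count can change results at that tolerance.
- CSV outputs use `%.6g` formatting and fixed column orders
  (`runtiming.io.SCHEMAS`), making pipeline runs byte-reproducible for
  a given seed.

## 8. Limitations

- The normal entry-curve assumption is structural; strongly bimodal
  runs would need a mixture extension.
- Stream-life enters as a deterministic schedule; individual
  stream-life variation is absorbed into the fit residuals rather than
  modeled.
- The heritability design estimates a realized (selection-response)
  h² from group means; it does not separate maternal or shared
  environmental effects from additive variance, and its CI assumes
  independent group-year points.
- Prespawning mortality is out of scope; live counts are assumed to be
  of eventual spawners.
- The break-year estimate for gentle slope kinks is intrinsically
  uncertain by a few years at realistic noise (§3); report it with the
  model-family weight, not as a point fact.
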