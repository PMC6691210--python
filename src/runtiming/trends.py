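"""Candidate trend models for median run timing.

Sixteen Gaussian linear models combine a stationary or linear year trend,
up to two environmental covariates (E1, E2), and an optional regime break
(R = 0 before the break year, 1 from it onward) with the corresponding
interactions. Break years are found by exhaustive scan; models are
compared by AIC and Akaike weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class CandidateSpec:
    """One candidate: which terms enter besides the intercept."""

    id: str
    has_break: bool
    terms: tuple[str, ...]

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if t in ("E1", "E2"))


CANDIDATES: dict[str, CandidateSpec] = {
    "1a": CandidateSpec("1a", False, ()),
    "1b": CandidateSpec("1b", False, ("E1",)),
    "1c": CandidateSpec("1c", False, ("E2",)),
    "1d": CandidateSpec("1d", False, ("E1", "E2")),
    "2a": CandidateSpec("2a", True, ("R",)),
    "2b": CandidateSpec("2b", True, ("E1", "R", "E1:R")),
    "2c": CandidateSpec("2c", True, ("E2", "R", "E2:R")),
    "2d": CandidateSpec("2d", True, ("E1", "E2", "R", "E1:R", "E2:R")),
    "3a": CandidateSpec("3a", False, ("Y",)),
    "3b": CandidateSpec("3b", False, ("Y", "E1")),
    "3c": CandidateSpec("3c", False, ("Y", "E2")),
    "3d": CandidateSpec("3d", False, ("Y", "E1", "E2")),
    "4a": CandidateSpec("4a", True, ("R", "Y", "R:Y")),
    "4b": CandidateSpec("4b", True, ("R", "Y", "E1", "R:Y", "R:E1")),
    "4c": CandidateSpec("4c", True, ("R", "Y", "E2", "R:Y", "R:E2")),
    "4d": CandidateSpec("4d", True,
                        ("R", "Y", "E1", "E2", "R:Y", "R:E1", "R:E2")),
}

MIN_SEGMENT = 3   # observations required on each side of a break


@dataclass
class ModelFit:
    spec_id: str
    break_year: int | None
    coefficients: dict[str, float]
    aic: float
    loglik: float
    n: int
    rss: float
    delta_aic: float = float("nan")
    akaike_weight: float = float("nan")

    @property
    def k(self) -> int:
        """Parameter count: coefficients plus the error variance."""
        return len(self.coefficients) + 1


def _base_columns(df: pd.DataFrame, break_year: int | None) -> pd.DataFrame:
    cols = {"Y": df["year"].astype(float)}
    if break_year is not None:
        cols["R"] = (df["year"] >= break_year).astype(float)
    for c in ("E1", "E2"):
        if c in df.columns:
            cols[c] = df[c].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _design(df: pd.DataFrame, spec: CandidateSpec,
            break_year: int | None, standardized: bool) -> pd.DataFrame:
    base = _base_columns(df, break_year)
    if standardized:
        for c in ("E1", "E2"):
            if c in base:
                sd = base[c].std(ddof=0)
                base[c] = (base[c] - base[c].mean()) / (sd if sd > 0 else 1.0)
        base["Y"] = base["Y"] - base["Y"].mean()
    out = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for term in spec.terms:
        if ":" in term:
            a, b = term.split(":")
            out[term] = base[a] * base[b]
        else:
            out[term] = base[term]
    return out


def _assemble(timing: pd.Series, covars: pd.DataFrame | None,
              spec: CandidateSpec) -> pd.DataFrame:
    df = pd.DataFrame({"year": timing.index.astype(int),
                       "y": timing.to_numpy(float)})
    for c in spec.covariates:
        if covars is None or c not in covars.columns:
            raise ValueError(f"model {spec.id} needs covariate {c}")
        df[c] = covars[c].reindex(df["year"]).to_numpy()
    return df.dropna().reset_index(drop=True)


def fit_candidate(timing: pd.Series, covars: pd.DataFrame | None,
                  spec: CandidateSpec,
                  break_year: int | None = None) -> ModelFit:
    """Fit one candidate by Gaussian maximum likelihood.

    ``timing`` is a year-indexed series of median dates; ``covars`` a
    year-indexed frame with E1/E2 columns. AIC counts the error variance
    as a parameter (2k − 2 lnL with k = coefficients + 1), matching the
    convention of R's AIC for linear models. Covariates are z-scored for
    conditioning; reported coefficients are on the original scale.
    """
    if spec.has_break and break_year is None:
        raise ValueError(f"model {spec.id} requires a break year")
    df = _assemble(timing, covars, spec)
    n = len(df)
    p = len(spec.terms) + 1
    if n < p + 3:
        raise ValueError(f"model {spec.id}: {n} complete years, "
                         f"need at least {p + 3}")
    Xz = _design(df, spec, break_year, standardized=True)
    rank = np.linalg.matrix_rank(Xz.to_numpy())
    if rank < Xz.shape[1]:
        bad = _collinear_terms(Xz)
        raise ValueError(f"model {spec.id}: rank-deficient design "
                         f"(collinear terms: {', '.join(bad)})")
    res = sm.OLS(df["y"].to_numpy(), Xz.to_numpy()).fit()
    fitted = res.fittedvalues
    rss = float(res.ssr)
    # back-transform: project fitted values onto the raw design (same
    # column space, so this recovers original-scale coefficients exactly)
    Xr = _design(df, spec, break_year, standardized=False)
    beta_raw, *_ = np.linalg.lstsq(Xr.to_numpy(), fitted, rcond=None)
    coefs = dict(zip(Xr.columns, map(float, beta_raw)))
    loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    aic = 2 * (p + 1) - 2 * loglik
    return ModelFit(spec.id, break_year if spec.has_break else None,
                    coefs, float(aic), float(loglik), n, rss)


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    bad = [col for col in X.columns
           if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy())
           == full_rank]
    return bad or list(X.columns)


def _per_segment_params(spec: CandidateSpec) -> int:
    """Coefficients each regime must support on its own: the intercept
    plus every term that also has an R interaction (fully interacted
    terms make each segment an independent regression)."""
    pairs = {frozenset(t.split(":")) for t in spec.terms if ":" in t}
    return 1 + sum(1 for t in ("Y", "E1", "E2")
                   if t in spec.terms and frozenset((t, "R")) in pairs)


def feasible_break_years(years: np.ndarray,
                         min_segment: int = MIN_SEGMENT) -> list[int]:
    """Break years leaving at least ``min_segment`` observations strictly
    before and at/after the break."""
    years = np.sort(np.asarray(years, dtype=int))
    return [int(b) for b in years
            if (years < b).sum() >= min_segment
            and (years >= b).sum() >= min_segment]


def breakpoint_search(timing: pd.Series, covars: pd.DataFrame | None,
                      spec: CandidateSpec) -> ModelFit:
    """Exhaustive break-year scan; returns the lowest-AIC fit, ties going
    to the earliest year.

    A segment must hold one more observation than its per-segment
    coefficient count (the simplest break model needs a line plus a
    residual on each side, i.e. 3 points); break years whose design is
    nonetheless rank-deficient are skipped.
    """
    if not spec.has_break:
        raise ValueError(f"model {spec.id} has no break term")
    df = _assemble(timing, covars, spec)
    min_side = max(MIN_SEGMENT, _per_segment_params(spec) + 1)
    breaks = feasible_break_years(df["year"].to_numpy(), min_side)
    if not breaks:
        raise ValueError(f"no feasible break year (need >={min_side} "
                         "observations on each side)")
    best: ModelFit | None = None
    for b in breaks:
        try:
            fit = fit_candidate(timing, covars, spec, break_year=b)
        except ValueError:
            continue
        if best is None or fit.aic < best.aic - 1e-12:
            best = fit
    if best is None:
        raise ValueError(f"model {spec.id}: every feasible break year "
                         "gave a degenerate design")
    return best


def fit_suite(timing: pd.Series, covars: pd.DataFrame | None = None,
              candidate_ids: list[str] | None = None) -> list[ModelFit]:
    """Fit every candidate (searching breaks where applicable)."""
    ids = candidate_ids or list(CANDIDATES)
    fits = []
    for cid in ids:
        spec = CANDIDATES[cid]
        if spec.has_break:
            fits.append(breakpoint_search(timing, covars, spec))
        else:
            fits.append(fit_candidate(timing, covars, spec))
    return fits


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Normalized relative likelihoods exp(−ΔAIC/2); invariant to adding
    a constant to every AIC."""
    aics = np.asarray(aics, dtype=float)
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


def model_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits by AIC and attach ΔAIC and Akaike weights."""
    if len(fits) < 1:
        raise ValueError("no fits to rank")
    aics = np.array([f.aic for f in fits])
    weights = akaike_weights(aics)
    best = aics.min()
    for f, w in zip(fits, weights):
        f.delta_aic = float(f.aic - best)
        f.akaike_weight = float(w)
    rows = [{
        "model_id": f.spec_id,
        "break_year": f.break_year,
        "aic": f.aic,
        "delta_aic": f.delta_aic,
        "weight": f.akaike_weight,
        "n": f.n,
        "coefficients": ";".join(f"{k}={v:.6g}"
                                 for k, v in f.coefficients.items()),
    } for f in fits]
    return (pd.DataFrame(rows).sort_values("aic").reset_index(drop=True))


def timing_correlations(metrics: dict[str, pd.Series],
                        min_overlap: int = 5) -> pd.DataFrame:
    """Pairwise-complete Pearson r between year-indexed timing metrics.

    Pairs with fewer than ``min_overlap`` shared years, or with zero
    variance, are NaN.
    """
    names = list(metrics)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            pair = pd.concat([metrics[a], metrics[b]], axis=1,
                             join="inner").dropna()
            if len(pair) < min_overlap:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                warnings.warn(f"zero variance in pair ({a}, {b})")
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out
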