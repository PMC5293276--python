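"""Classical small-area variation statistics.

The battery reported per condition and year: age/sex-standardized rates per
10,000 person-years (direct standardization), expected counts by internal
(indirect) standardization, standardized hospitalization ratios (SHR),
the extremal quotient after trimming the 5th/95th percentile tails
(EQ5-95), and McPherson's systematic component of variation (SCV), which
subtracts the Poisson noise floor from the between-area variance of O/E
ratios.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .panel import CountsPanel
from .population import StratifiedPopulation


class DataError(ValueError):
    """Raised for structurally invalid descriptive-statistics inputs."""


def direct_standardized_rate(
    counts: np.ndarray,
    person_years: np.ndarray,
    standard_population: np.ndarray,
) -> float:
    """Directly standardized rate per 10,000 person-years.

    ``sum_s w_s (c_s / n_s) / sum_s w_s * 1e4`` with weights ``w_s`` from the
    standard population.  Strata with zero person-years contribute 0 and
    raise a warning (their weight is still counted in the denominator).
    """
    c = np.asarray(counts, dtype=float)
    n = np.asarray(person_years, dtype=float)
    w = np.asarray(standard_population, dtype=float)
    if not (c.shape == n.shape == w.shape):
        raise DataError("counts, person_years and standard weights must align")
    if w.sum() <= 0:
        raise DataError("standard population total must be positive")
    empty = n == 0
    if np.any(empty & (c > 0)):
        raise DataError("events observed in a stratum with zero person-years")
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} strata with zero person-years contribute 0",
            stacklevel=2,
        )
    rates = np.where(empty, 0.0, np.divide(c, n, where=~empty, out=np.zeros_like(c)))
    return float((w * rates).sum() / w.sum() * 1e4)


def expected_counts(
    o_strat: np.ndarray, py_strat: np.ndarray
) -> np.ndarray:
    """Expected counts per (area, year) by internal indirect standardization.

    Stratum rates are pooled over *all* areas and years and applied to each
    cell's stratified person-years, so the expected counts sum exactly to the
    observed counts by construction.
    """
    o = np.asarray(o_strat, dtype=float)
    n = np.asarray(py_strat, dtype=float)
    if o.shape != n.shape or o.ndim != 3:
        raise DataError("stratified counts and person-years must align (I, T, S)")
    n_s = n.sum(axis=(0, 1))
    if n_s.sum() <= 0:
        raise DataError("all person-years are zero")
    if o.sum() < 1:
        raise DataError("need at least one observed event")
    o_s = o.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(n_s > 0, o_s / np.where(n_s > 0, n_s, 1.0), 0.0)
    return (n * rates[None, None, :]).sum(axis=2)


def shr(o: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Standardized hospitalization ratio o/e; NaN flags zero-exposure cells."""
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(e > 0, o / np.where(e > 0, e, 1.0), np.nan)
    return out


def extremal_quotient_5_95(
    rates: np.ndarray,
    *,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    method: str = "hazen",
) -> float:
    """Extremal quotient after trimming both percentile tails.

    Areas with a rate strictly below the ``lower_pct`` or strictly above the
    ``upper_pct`` empirical percentile are dropped; the ratio max/min of the
    survivors is returned.  The percentile convention (``method``, any numpy
    quantile method) defaults to Hazen plotting positions, under which the
    smallest/largest observations survive in tiny samples while a 5% tail is
    trimmed in large ones.  ``inf`` flags a surviving minimum of zero.
    """
    r = np.asarray(rates, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 2:
        raise DataError("extremal quotient needs at least 2 areas with rates")
    lo, hi = np.percentile(r, [lower_pct, upper_pct], method=method)
    keep = r[(r >= lo) & (r <= hi)]
    if keep.size == 0:  # pragma: no cover - inclusive endpoints prevent this
        raise DataError("no areas survive the percentile trim")
    mn, mx = keep.min(), keep.max()
    if mn == 0:
        return np.inf
    return float(mx / mn)


@dataclasses.dataclass(frozen=True)
class ScvResult:
    """SCV point value with a flag for negative-estimate truncation."""

    value: float
    truncated: bool

    def __float__(self) -> float:
        return self.value


def scv(o: np.ndarray, e: np.ndarray) -> ScvResult:
    """Systematic coefficient of variation of O/E ratios across areas.

    ``(1/k) sum_i [ (o_i - e_i)^2 / e_i^2 - 1/e_i ]``: the empirical variance
    of the SHRs minus the expected Poisson contribution.  The estimator is
    unbiased but can go negative in small samples; negative values are
    truncated to 0 with ``truncated=True``.
    """
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    if o.shape != e.shape:
        raise DataError("o and e must align")
    if o.size < 2:
        raise DataError("SCV needs at least 2 areas")
    if np.any(e <= 0):
        raise DataError("SCV requires positive expected counts in every area")
    raw = float(np.mean((o - e) ** 2 / e**2 - 1.0 / e))
    if raw < 0:
        return ScvResult(0.0, True)
    return ScvResult(raw, False)


def per_area_standardized_rates(
    panel: CountsPanel, pop: StratifiedPopulation
) -> np.ndarray:
    """Directly standardized rate per (area, year), per 10,000 person-years.

    The standard population is the pooled study population (all areas and
    years).  Falls back to crude rates when stratified counts are absent.
    """
    I, T = panel.o.shape
    if panel.o_strat is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                panel.person_years > 0,
                panel.o / np.where(panel.person_years > 0, panel.person_years, 1.0),
                np.nan,
            ) * 1e4
    w = pop.person_years.sum(axis=(0, 1))
    out = np.empty((I, T))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(I):
            for t in range(T):
                out[i, t] = direct_standardized_rate(
                    panel.o_strat[i, t], pop.person_years[i, t], w
                )
    return out


def variation_table(panel: CountsPanel, pop: StratifiedPopulation) -> pd.DataFrame:
    """Per-year variation battery: cases, standardized rate, EQ5-95, SCV.

    With a single area the spread statistics are undefined and reported as
    NaN while the rates are still produced.
    """
    I, T = panel.o.shape
    rates_it = per_area_standardized_rates(panel, pop)
    if panel.o_strat is not None:
        e_int = expected_counts(panel.o_strat, pop.person_years)
    else:
        e_int = panel.e
    w = pop.person_years.sum(axis=(0, 1))
    rows = []
    for t, year in enumerate(panel.years):
        cases = int(panel.o[:, t].sum())
        if panel.o_strat is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rate = direct_standardized_rate(
                    panel.o_strat[:, t].sum(axis=0),
                    pop.person_years[:, t].sum(axis=0),
                    w,
                )
        else:
            py = panel.person_years[:, t].sum()
            rate = float(panel.o[:, t].sum() / py * 1e4) if py > 0 else np.nan
        if I >= 2:
            eq = extremal_quotient_5_95(rates_it[:, t])
            ok = e_int[:, t] > 0
            s = scv(panel.o[ok, t], e_int[ok, t]) if ok.sum() >= 2 else None
        else:
            eq, s = np.nan, None
        rows.append(
            {
                "year": year,
                "cases": cases,
                "rate_per_10k": rate,
                "eq5_95": eq,
                "scv": np.nan if s is None else s.value,
                "scv_truncated": False if s is None else s.truncated,
            }
        )
    return pd.DataFrame(rows)
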