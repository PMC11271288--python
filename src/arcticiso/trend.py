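"""Long-term emission trends: annual integration, OLS slope, Mann–Kendall.

Annual site-scale emissions (mg m⁻² yr⁻¹) are obtained by driving the
flux model with a multi-year met series under either the default or the
updated (sedge/willow) temperature responses and integrating each
calendar year.  Trends are summarised by the ordinary least-squares slope
and the nonparametric Mann–Kendall test:

    S = Σ_{i<j} sign(x_j − x_i)

with the tie-corrected normal approximation (continuity-corrected) for the
p-value, replaced by the exact null distribution for short series
(n ≤ 10, no ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    ActivityFactors,
    DefaultResponseParams,
    ISOPRENE_MOLAR_MASS,
    SedgeResponseParams,
    WillowCapacityParams,
)
from .site import FluxSeries, SitePFT, model_flux

__all__ = ["AnnualSeries", "TrendResult", "annual_emissions", "mann_kendall",
           "linear_trend"]

EXACT_N_MAX = 10


@dataclass(frozen=True)
class TrendResult:
    slope: float       # emission units per year
    intercept: float
    mk_s: int
    mk_tau: float
    p_value: float

    def __post_init__(self):
        if not -1 - 1e-12 <= self.mk_tau <= 1 + 1e-12:
            raise ValueError("tau must lie in [-1, 1]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class AnnualSeries:
    """Annual totals: emission (mg m⁻² yr⁻¹) and mean air temperature (K)."""

    years: np.ndarray
    emission: np.ndarray
    mean_t_air: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.years, int)
        if np.any(np.diff(y) <= 0):
            raise ValueError("years must be strictly increasing without duplicates")


def _pfts_for_model(pfts, model: str):
    """Response kinds per model variant: 'updated' keeps the Arctic kinds,
    'default' evaluates every PFT with the default MEGAN curve."""
    if model == "updated":
        return list(pfts)
    if model == "default":
        return [
            SitePFT(p.name, p.leaf_ef, "default", p.cover_fraction) for p in pfts
        ]
    raise ValueError("model must be 'default' or 'updated'")


def annual_emissions(
    series: FluxSeries,
    pfts,
    model: str = "updated",
    factors: ActivityFactors = ActivityFactors(),
    default_params: DefaultResponseParams = DefaultResponseParams(),
    sedge_params: SedgeResponseParams = SedgeResponseParams(),
    willow_params: WillowCapacityParams = WillowCapacityParams(),
    min_coverage: float = 0.95,
) -> AnnualSeries:
    """Integrate modelled flux to annual totals (mg m⁻² yr⁻¹).

    Trapezoidal integration over the half-hourly series, converted to mass
    via the isoprene molar mass (68.12 g mol⁻¹).  Years whose usable
    (post-spin-up) coverage falls below ``min_coverage`` are dropped with
    a warning.
    """
    flux = model_flux(
        series, _pfts_for_model(pfts, model), factors,
        default_params, sedge_params, willow_params,
    )
    t_air = series.data["t_air"]
    years, totals, tmeans = [], [], []
    for year, grp in flux.groupby(flux.index.year):
        expected = pd.Timestamp(year=year + 1, month=1, day=1) - pd.Timestamp(
            year=year, month=1, day=1
        )
        step = grp.index.to_series().diff().mode().iloc[0]
        coverage = len(grp.dropna()) * step / expected
        if coverage < min_coverage:
            warnings.warn(
                f"dropping year {year}: coverage {coverage:.2f} < {min_coverage}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        g = grp.dropna()
        seconds = (g.index - g.index[0]).total_seconds()
        nmol = np.trapezoid(g.to_numpy(float), seconds)  # nmol m⁻²
        totals.append(nmol * ISOPRENE_MOLAR_MASS * 1e-6)  # mg m⁻²
        years.append(year)
        tmeans.append(float(t_air[flux.index.year == year].mean()))
    return AnnualSeries(np.array(years), np.array(totals), np.array(tmeans))


def _mk_s_and_ties(x: np.ndarray) -> tuple[int, np.ndarray]:
    diff = np.sign(np.subtract.outer(x, x))
    s = int(np.triu(diff.T, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    return s, counts[counts > 1]


def mann_kendall(series) -> TrendResult:
    """Mann–Kendall monotonic-trend test with OLS slope attached.

    ``tau`` is Kendall's tau-b (tie-corrected; equal to S/(n(n−1)/2)
    without ties).  The p-value uses the exact null distribution for
    n ≤ 10 without ties, otherwise the tie-adjusted normal approximation
    with continuity correction.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    s, ties = _mk_s_and_ties(x)
    d = n * (n - 1) / 2
    tie_pairs = (ties * (ties - 1) / 2).sum()
    denom = np.sqrt(d * (d - tie_pairs))
    tau = s / denom if denom > 0 else 0.0
    if np.ptp(x) == 0:
        p = 1.0
    elif n <= EXACT_N_MAX and len(ties) == 0:
        # Exact null distribution of S for distinct values.
        p = float(stats.kendalltau(np.arange(n), x, method="exact").pvalue)
    else:
        var = (n * (n - 1) * (2 * n + 5) - (ties * (ties - 1) * (2 * ties + 5)).sum()) / 18
        if var <= 0:
            p = 1.0
        else:
            z = (s - np.sign(s)) / np.sqrt(var) if s != 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z)))
    slope, intercept = _ols_line(np.arange(n, dtype=float), x)
    return TrendResult(slope=slope, intercept=intercept, mk_s=s,
                       mk_tau=float(tau), p_value=min(p, 1.0))


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(y) == 0:
        return 0.0, float(y[0])
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept)


def linear_trend(series: AnnualSeries | np.ndarray) -> float:
    """OLS slope of annual emission on year (emission units yr⁻¹)."""
    if isinstance(series, AnnualSeries):
        t = np.asarray(series.years, dtype=float)
        y = np.asarray(series.emission, dtype=float)
    else:
        y = np.asarray(series, dtype=float).reshape(-1)
        t = np.arange(len(y), dtype=float)
    if len(y) < 3:
        raise ValueError(f"need n >= 3, got {len(y)}")
    return _ols_line(t, y)[0]
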