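"""Site-level isoprene flux as a mixture of plant-functional-type responses.

The half-hourly ecosystem flux is modelled as

    F = Σ_i  E_i · (LAI/LAI_max) · γ_T_i · γ_others,     E_i = ε*_i · CF_i

where ε*_i is the canopy-level emission factor of vegetation type i
(leaf-level EF scaled to the LAI = 5 standard canopy: ε* = EF_leaf·5·Cce,
so the canopy factor Cce enters exactly once), CF_i its cover fraction,
γ_T_i the temperature activity dispatched by response kind (default /
sedge / willow), and γ_others the product of the remaining activity
factors (light, leaf age, CO₂, soil moisture; all 1 by default, with the
PPFD > 300 µmol m⁻² s⁻¹ daytime filter standing in for an explicit light
response).  Cover fractions (or total capacities E_i) are recovered by
bounded least squares against eddy-covariance observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .arctic import RESPONSE_KINDS, gamma_t
from .params import (
    ActivityFactors,
    DefaultResponseParams,
    ISOPRENE_MOLAR_MASS,
    SedgeResponseParams,
    WillowCapacityParams,
)
from .response import TemperatureHistory, trailing_means

__all__ = [
    "SitePFT",
    "FluxSeries",
    "FitResult",
    "CollinearityError",
    "canopy_ef",
    "model_flux",
    "CoverFractionModel",
    "fit_cover_fractions",
    "evaluate",
    "read_flux_csv",
]

LAI_STANDARD = 5.0          # m² m⁻², MEGAN standard-canopy scenario
DEFAULT_PPFD_MIN = 300.0    # µmol m⁻² s⁻¹, strict ">" filter
# mg m⁻² h⁻¹ → nmol m⁻² s⁻¹
MG_H_TO_NMOL_S = 1e6 / (ISOPRENE_MOLAR_MASS * 3600.0)


class CollinearityError(ValueError):
    """Raised when per-PFT basis fluxes are too collinear to separate."""


def canopy_ef(leaf_ef: float, lai_std: float = LAI_STANDARD, cce: float = 0.3) -> float:
    """Canopy-level emission factor from a leaf-level one (LAI = 5 scenario)."""
    if leaf_ef <= 0:
        raise ValueError(f"leaf_ef must be positive, got {leaf_ef}")
    return leaf_ef * lai_std * cce


@dataclass(frozen=True)
class SitePFT:
    """A vegetation type at a site: emission factor, response kind, cover."""

    name: str
    leaf_ef: float                      # nmol m⁻² s⁻¹
    response_kind: str = "default"
    cover_fraction: float | None = None

    def __post_init__(self):
        if self.leaf_ef <= 0:
            raise ValueError(f"{self.name}: leaf_ef must be positive")
        if self.response_kind not in RESPONSE_KINDS:
            raise ValueError(
                f"{self.name}: response_kind must be one of {RESPONSE_KINDS}"
            )
        if self.cover_fraction is not None and not 0 <= self.cover_fraction <= 1:
            raise ValueError(f"{self.name}: cover_fraction must lie in [0, 1]")

    def canopy_ef(self, lai_std: float = LAI_STANDARD, cce: float = 0.3) -> float:
        return canopy_ef(self.leaf_ef, lai_std, cce)


@dataclass
class FluxSeries:
    """Half-hourly site observations with derived acclimation temperatures.

    ``data`` columns: ``flux`` (nmol m⁻² s⁻¹, may be absent for pure
    forward runs), ``t_air`` (K), optional ``t_leaf`` (K), ``ppfd``
    (µmol m⁻² s⁻¹), ``lai``; plus ``t24``/``t240`` (K, NaN during the
    240-h spin-up).  Index: regular DatetimeIndex.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"t_air", "ppfd", "lai"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"FluxSeries missing columns: {sorted(missing)}")
        if (self.data["lai"] < 0).any():
            raise ValueError("LAI must be >= 0")
        if not (self.data["lai"] > 0).any():
            raise ValueError("LAI must be positive somewhere in the record")
        if not {"t24", "t240"} <= set(self.data.columns):
            tm = trailing_means(self.data["t_air"])
            self.data = self.data.join(tm)

    @classmethod
    def from_met(cls, met: pd.DataFrame, flux: pd.Series | None = None) -> "FluxSeries":
        df = met.copy()
        if flux is not None:
            df["flux"] = flux
        return cls(df)

    @property
    def lai_max(self) -> float:
        return float(self.data["lai"].max())

    @property
    def temperature(self) -> pd.Series:
        """Driving temperature for γ_T: leaf if present, else air."""
        col = "t_leaf" if "t_leaf" in self.data.columns else "t_air"
        return self.data[col]

    def usable(self) -> pd.Series:
        """Boolean mask of rows with acclimation available."""
        return self.data["t24"].notna() & self.data["t240"].notna()


@dataclass(frozen=True)
class FitResult:
    """Cover-fraction (or capacity) fit against observed flux."""

    pft_names: tuple[str, ...]
    cover_fractions: np.ndarray | None
    capacities: np.ndarray          # E_i, nmol m⁻² s⁻¹
    r_squared: float
    rmse: float
    n_obs: int
    residuals: pd.Series = field(repr=False, default=None)

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def _basis_matrix(
    series: FluxSeries,
    pfts,
    factors: ActivityFactors,
    default_params,
    sedge_params,
    willow_params,
) -> tuple[np.ndarray, pd.Series]:
    """Per-PFT flux at CF = 1 (columns) for every timestamp with acclimation."""
    ok = series.usable()
    t = series.temperature[ok].to_numpy(float)
    hist = TemperatureHistory(
        t=t,
        t24=series.data.loc[ok, "t24"].to_numpy(float),
        t240=series.data.loc[ok, "t240"].to_numpy(float),
    )
    lai_ratio = (series.data.loc[ok, "lai"] / series.lai_max).to_numpy(float)
    cols = []
    for p in pfts:
        g = gamma_t(
            p.response_kind,
            hist,
            default_params=default_params,
            sedge_params=sedge_params,
            willow_params=willow_params,
        )
        cols.append(
            p.canopy_ef(cce=factors.cce) * lai_ratio * g * factors.gamma_others
        )
    return np.column_stack(cols), ok


def model_flux(
    series: FluxSeries,
    pfts,
    factors: ActivityFactors = ActivityFactors(),
    default_params: DefaultResponseParams = DefaultResponseParams(),
    sedge_params: SedgeResponseParams = SedgeResponseParams(),
    willow_params: WillowCapacityParams = WillowCapacityParams(),
) -> pd.Series:
    """Forward-model the site flux (nmol m⁻² s⁻¹) for PFTs with known cover.

    Timestamps lacking acclimation means (240-h spin-up) are NaN.
    """
    if not pfts:
        raise ValueError("PFT list must be nonempty")
    for p in pfts:
        if p.cover_fraction is None:
            raise ValueError(f"{p.name}: cover_fraction required for forward model")
    basis, ok = _basis_matrix(
        series, pfts, factors, default_params, sedge_params, willow_params
    )
    cf = np.array([p.cover_fraction for p in pfts])
    out = pd.Series(np.nan, index=series.data.index, name="flux_model")
    out[ok] = basis @ cf
    return out


class CoverFractionModel(RegressorMixin, BaseEstimator):
    """Bounded least-squares mixture fit of PFT cover fractions.

    ``mode="cf"`` solves for cover fractions CF_i ∈ [0, 1] with the
    canopy emission factors fixed; ``mode="ei"`` solves for the total
    capacities E_i ≥ 0 directly (the default-model variant, absorbing the
    emission factor into the unknown).  Only rows with
    PPFD > ``ppfd_min`` and available acclimation are used.

    Fitted attributes: ``cover_fractions_`` (cf mode), ``capacities_``,
    ``r_squared_`` (squared Pearson correlation by default),
    ``rmse_``, ``n_obs_``, ``residuals_``.
    """

    def __init__(
        self,
        pfts=(),
        mode: str = "cf",
        ppfd_min: float = DEFAULT_PPFD_MIN,
        sum_constraint: bool = False,
        factors: ActivityFactors = ActivityFactors(),
        default_params: DefaultResponseParams = DefaultResponseParams(),
        sedge_params: SedgeResponseParams = SedgeResponseParams(),
        willow_params: WillowCapacityParams = WillowCapacityParams(),
        cond_max: float = 1e8,
        r2_kind: str = "pearson",
    ):
        self.pfts = pfts
        self.mode = mode
        self.ppfd_min = ppfd_min
        self.sum_constraint = sum_constraint
        self.factors = factors
        self.default_params = default_params
        self.sedge_params = sedge_params
        self.willow_params = willow_params
        self.cond_max = cond_max
        self.r2_kind = r2_kind

    def fit(self, X: FluxSeries, y=None):
        series = X
        if not self.pfts:
            raise ValueError("PFT list must be nonempty")
        if self.mode not in ("cf", "ei"):
            raise ValueError("mode must be 'cf' or 'ei'")
        obs = series.data["flux"] if y is None else pd.Series(y, index=series.data.index)
        basis, ok = _basis_matrix(
            series, self.pfts, self.factors,
            self.default_params, self.sedge_params, self.willow_params,
        )
        keep = (
            (series.data.loc[ok, "ppfd"] > self.ppfd_min)
            & obs[ok].notna()
        ).to_numpy()
        A = basis[keep]
        b = obs[ok].to_numpy(float)[keep]
        if len(b) < 10:
            raise ValueError(
                f"only {len(b)} observations survive the PPFD > {self.ppfd_min} "
                "filter; need at least 10"
            )
        if self.mode == "ei":
            # Unknowns are the capacities themselves: strip the EF scaling.
            efs = np.array([p.canopy_ef(cce=self.factors.cce) for p in self.pfts])
            A = A / efs
        scale = np.linalg.norm(A, axis=0)
        if np.any(scale == 0):
            cond = np.inf
        else:
            cond = np.linalg.cond(A / scale)
        if not np.isfinite(cond) or cond > self.cond_max:
            raise CollinearityError(
                f"PFT basis fluxes are collinear (condition number {cond:.3g}); "
                "merge indistinguishable PFTs or change their response kinds"
            )
        upper = 1.0 if self.mode == "cf" else np.inf
        res = optimize.lsq_linear(A, b, bounds=(0.0, upper))
        coef = res.x
        if self.mode == "cf" and self.sum_constraint and coef.sum() > 1.0:
            # Project onto the simplex face via scaled bounds refit.
            res = optimize.lsq_linear(
                np.vstack([A, np.full((1, A.shape[1]), 1e6)]),
                np.concatenate([b, [1e6]]),
                bounds=(0.0, 1.0),
            )
            coef = res.x
        fitted = A @ coef
        self.r_squared_, self.rmse_ = evaluate(fitted, b, r2_kind=self.r2_kind)
        self.n_obs_ = int(len(b))
        if self.mode == "cf":
            self.cover_fractions_ = coef
            efs = np.array([p.canopy_ef(cce=self.factors.cce) for p in self.pfts])
            self.capacities_ = coef * efs
        else:
            self.cover_fractions_ = None
            self.capacities_ = coef
        idx = series.data.index[ok.to_numpy()][keep]
        self.residuals_ = pd.Series(b - fitted, index=idx, name="residual")
        return self

    def predict(self, X: FluxSeries) -> pd.Series:
        coef = (
            self.cover_fractions_ if self.cover_fractions_ is not None
            else self.capacities_
        )
        basis, ok = _basis_matrix(
            X, self.pfts, self.factors,
            self.default_params, self.sedge_params, self.willow_params,
        )
        if self.cover_fractions_ is None:
            efs = np.array([p.canopy_ef(cce=self.factors.cce) for p in self.pfts])
            basis = basis / efs
        out = pd.Series(np.nan, index=X.data.index, name="flux_model")
        out[ok] = basis @ coef
        return out


def fit_cover_fractions(
    obs: FluxSeries,
    pfts,
    ppfd_min: float = DEFAULT_PPFD_MIN,
    mode: str = "cf",
    **kwargs,
) -> FitResult:
    """Fit PFT cover fractions (or capacities) to observed half-hourly flux."""
    m = CoverFractionModel(pfts=pfts, mode=mode, ppfd_min=ppfd_min, **kwargs).fit(obs)
    return FitResult(
        pft_names=tuple(p.name for p in pfts),
        cover_fractions=m.cover_fractions_,
        capacities=m.capacities_,
        r_squared=m.r_squared_,
        rmse=m.rmse_,
        n_obs=m.n_obs_,
        residuals=m.residuals_,
    )


def evaluate(modeled, observed, aggregate: str | None = None,
             r2_kind: str = "pearson") -> tuple[float, float]:
    """R² and RMSE of modeled vs observed flux.

    ``r2_kind="pearson"`` (default) is the squared Pearson correlation —
    the scatter-plot convention; ``"ss"`` gives 1 − SSE/SST.  With
    ``aggregate="daily"`` both series are daily-mean aggregated before
    scoring (requires DatetimeIndex-ed Series).
    """
    if aggregate not in (None, "none", "daily"):
        raise ValueError("aggregate must be None or 'daily'")
    if aggregate == "daily":
        modeled = pd.Series(modeled).resample("1D").mean().dropna()
        observed = pd.Series(observed).resample("1D").mean().dropna()
        common = modeled.index.intersection(observed.index)
        modeled, observed = modeled[common], observed[common]
    m = np.asarray(modeled, dtype=float).reshape(-1)
    o = np.asarray(observed, dtype=float).reshape(-1)
    if m.shape != o.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {o.shape}")
    if len(m) < 2:
        raise ValueError("need at least 2 aligned values")
    keep = np.isfinite(m) & np.isfinite(o)
    m, o = m[keep], o[keep]
    rmse = float(np.sqrt(np.mean((m - o) ** 2)))
    if r2_kind == "pearson":
        if np.ptp(m) == 0 or np.ptp(o) == 0:
            r2 = 1.0 if rmse == 0 or np.ptp(m) == np.ptp(o) == 0 else 0.0
        else:
            r2 = float(stats.pearsonr(m, o)[0] ** 2)
    elif r2_kind == "ss":
        sst = float(np.sum((o - o.mean()) ** 2))
        r2 = 1.0 - float(np.sum((m - o) ** 2)) / sst if sst > 0 else 0.0
    else:
        raise ValueError("r2_kind must be 'pearson' or 'ss'")
    return r2, rmse


def read_flux_csv(path, temp_unit: str = "C") -> FluxSeries:
    """Read the site flux/met CSV dialect into a FluxSeries.

    Columns: ``timestamp`` (ISO 8601), ``flux``, ``flux_units``
    (nmol_m2_s | mg_m2_h), ``t_air``, optional ``t_leaf``, ``ppfd``,
    ``lai``.  mg m⁻² h⁻¹ fluxes are converted with the isoprene molar
    mass 68.12 g mol⁻¹.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
    if "flux_units" in df.columns:
        units = df.pop("flux_units")
        bad = set(units.dropna().unique()) - {"nmol_m2_s", "mg_m2_h"}
        if bad:
            raise ValueError(f"unknown flux_units: {sorted(bad)}")
        if "flux" in df.columns:
            mask = units == "mg_m2_h"
            df.loc[mask, "flux"] = df.loc[mask, "flux"] * MG_H_TO_NMOL_S
    if temp_unit == "C":
        for col in ("t_air", "t_leaf"):
            if col in df.columns:
                df[col] = df[col] + 273.15
    elif temp_unit != "K":
        raise ValueError("temp_unit must be 'C' or 'K'")
    return FluxSeries(df)
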