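"""Fitting leaf-chamber temperature-ramp experiments.

Each chamber experiment ramps leaf temperature stepwise (typically 15/20 →
35/40 °C in 5 °C steps) and records the isoprene emission rate at each
step.  The exponential part of the response is summarised by an Arrhenius
fit in log space:

    ln E = ln EF30 + Ea/R · (1/303.15 − 1/T)

so the slope of ln E on x = (1/303.15 − 1/T)/R is the activation energy Ea
(kJ mol⁻¹) and the intercept exponentiates to the standard-condition
emission factor EF30 (30 °C).  Fits across experiments are then related to
the plants' recent thermal history: lag correlation against the mean air
temperature of the preceding 1..15 days, and nonlinear recovery of the
acclimation curves linking Ea and EF30 to the 10-day mean T240.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .params import GAS_CONSTANT_KJ, SedgeResponseParams, T_STANDARD

__all__ = [
    "ChamberExperiment",
    "ArrheniusFit",
    "ArrheniusRegressor",
    "fit_arrhenius",
    "q10_from_steps",
    "history_correlation",
    "ActivationAcclimationModel",
    "CapacityAcclimationModel",
    "fit_acclimation",
    "read_chamber_csv",
]

DEFAULT_T_MAX = 308.15  # K (35 °C): upper fit bound; behaviour degrades beyond 40 °C


@dataclass(frozen=True)
class ChamberExperiment:
    """One plant's temperature-step emissions plus its thermal history.

    ``prior_daily_means[k-1]`` is the daily-mean air temperature k days
    before the experiment (K), most recent first.
    """

    species_label: str
    temps_k: np.ndarray
    emissions: np.ndarray  # nmol m⁻² s⁻¹
    ppfd: float = 1000.0   # µmol m⁻² s⁻¹, metadata only
    prior_daily_means: np.ndarray | None = None
    experiment_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.temps_k, dtype=float)
        e = np.asarray(self.emissions, dtype=float)
        object.__setattr__(self, "temps_k", t)
        object.__setattr__(self, "emissions", e)
        if self.prior_daily_means is not None:
            object.__setattr__(
                self, "prior_daily_means", np.asarray(self.prior_daily_means, float)
            )
        if t.shape != e.shape:
            raise ValueError("temps_k and emissions must have equal length")
        if len(np.unique(t)) < 2:
            raise ValueError("need at least 2 distinct step temperatures")
        if np.any(np.diff(t) < 0):
            raise ValueError("steps must be sorted ascending in temperature")
        if np.any(e < 0):
            raise ValueError("emission rates must be >= 0")


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius summary of one experiment."""

    ea: float          # kJ mol⁻¹
    ef30: float        # nmol m⁻² s⁻¹ at 303.15 K
    r_squared: float
    n_points: int
    t_range: tuple[float, float]
    n_excluded: int = 0

    def __post_init__(self):
        if self.ef30 <= 0:
            raise ValueError("EF30 must be positive")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


class ArrheniusRegressor(RegressorMixin, BaseEstimator):
    """Log-space Arrhenius regression of emission rate on leaf temperature.

    Ordinary least squares of ln(emission) on (1/T_std − 1/T)/R: exact and
    deterministic on log-linear data, no solver tuning.  Steps above
    ``t_max`` are excluded (counted in ``n_excluded_``); non-positive
    emissions are dropped with a warning.

    Attributes (after ``fit``): ``activation_energy_`` (kJ mol⁻¹),
    ``ef30_`` (emission at 303.15 K), ``r_squared_``, ``n_points_``,
    ``t_range_``, ``n_excluded_``.
    """

    def __init__(self, t_max: float = DEFAULT_T_MAX,
                 t_std: float = T_STANDARD, r_gas: float = GAS_CONSTANT_KJ):
        self.t_max = t_max
        self.t_std = t_std
        self.r_gas = r_gas

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        e = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != e.shape:
            raise ValueError("X and y must have equal length")
        in_range = t <= self.t_max
        n_excluded = int((~in_range).sum())
        t, e = t[in_range], e[in_range]
        positive = e > 0
        if (~positive).any():
            warnings.warn(
                f"dropping {(~positive).sum()} non-positive emission step(s) "
                "from the Arrhenius fit",
                RuntimeWarning,
                stacklevel=2,
            )
            t, e = t[positive], e[positive]
        if len(np.unique(t)) < 2:
            raise ValueError(
                "need at least 2 usable steps with distinct temperatures "
                f"<= t_max={self.t_max} K and positive emission"
            )
        x = (1.0 / self.t_std - 1.0 / t) / self.r_gas
        res = stats.linregress(x, np.log(e))
        self.activation_energy_ = float(res.slope)
        self.ef30_ = float(np.exp(res.intercept))
        self.r_squared_ = float(res.rvalue**2)
        self.n_points_ = int(len(t))
        self.n_excluded_ = n_excluded
        self.t_range_ = (float(t.min()), float(t.max()))
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        return self.ef30_ * np.exp(
            self.activation_energy_ / self.r_gas * (1.0 / self.t_std - 1.0 / t)
        )


def fit_arrhenius(exp: ChamberExperiment, t_max: float = DEFAULT_T_MAX) -> ArrheniusFit:
    """Arrhenius fit of one chamber experiment (steps above ``t_max`` excluded)."""
    reg = ArrheniusRegressor(t_max=t_max).fit(exp.temps_k, exp.emissions)
    return ArrheniusFit(
        ea=reg.activation_energy_,
        ef30=reg.ef30_,
        r_squared=reg.r_squared_,
        n_points=reg.n_points_,
        t_range=reg.t_range_,
        n_excluded=reg.n_excluded_,
    )


def q10_from_steps(
    exp: ChamberExperiment,
    t1: float = 298.15,
    t2: float = 308.15,
    tol: float = 0.5,
) -> float:
    """Q10 from two measured steps, exponent-corrected if |t2−t1| ≠ 10 K."""
    def pick(target: float) -> float:
        d = np.abs(exp.temps_k - target)
        i = int(np.argmin(d))
        if d[i] > tol:
            raise ValueError(
                f"no step within {tol} K of {target} K "
                f"(available: {np.round(exp.temps_k, 2).tolist()})"
            )
        return float(exp.emissions[i]), float(exp.temps_k[i])

    e1, ta = pick(t1)
    e2, tb = pick(t2)
    if e1 <= 0 or e2 <= 0:
        raise ValueError("emissions at both bracket steps must be positive")
    return (e2 / e1) ** (10.0 / (tb - ta))


def history_correlation(
    fits: Sequence[tuple[ArrheniusFit, np.ndarray]],
    max_lag: int = 15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Lag correlation of fitted Ea and EF30 with preceding temperatures.

    For each lag k in 1..max_lag the predictor is the mean of the most
    recent k daily-mean temperatures.  Returns one row per lag with Pearson
    r and its t-test p-value for each response; ``best_lag`` (argmax |r|)
    is stored in ``DataFrame.attrs`` per response, alongside whether it is
    significant at ``alpha``.  r is NaN where a predictor or response is
    constant.
    """
    if len(fits) < 3:
        raise ValueError(f"need at least 3 experiments, got {len(fits)}")
    hist = []
    for f, days in fits:
        days = np.asarray(days, dtype=float)
        if len(days) < max_lag:
            raise ValueError(
                f"each experiment needs >= {max_lag} prior daily means, got {len(days)}"
            )
        hist.append(days[:max_lag])
    hist = np.asarray(hist)
    ea = np.array([f.ea for f, _ in fits])
    ef = np.array([f.ef30 for f, _ in fits])

    rows = []
    for k in range(1, max_lag + 1):
        pred = hist[:, :k].mean(axis=1)
        row = {"lag_days": k}
        for name, resp in (("ea", ea), ("ef30", ef)):
            if np.ptp(pred) == 0 or np.ptp(resp) == 0:
                row[f"r_{name}"] = np.nan
                row[f"p_{name}"] = np.nan
            else:
                r, p = stats.pearsonr(pred, resp)
                row[f"r_{name}"] = r
                row[f"p_{name}"] = p
        rows.append(row)
    table = pd.DataFrame(rows).set_index("lag_days")
    for name in ("ea", "ef30"):
        r = table[f"r_{name}"]
        if r.notna().any():
            best = int(r.abs().idxmax())
            table.attrs[f"best_lag_{name}"] = best
            table.attrs[f"significant_{name}"] = bool(
                table.loc[best, f"p_{name}"] < alpha
            )
        else:
            table.attrs[f"best_lag_{name}"] = None
            table.attrs[f"significant_{name}"] = False
    return table


class ActivationAcclimationModel(RegressorMixin, BaseEstimator):
    """Nonlinear fit of activation energy vs 10-day mean temperature.

    Model: Ea(T240) = c_base + amp·exp(rate·(t240_ref − T240)), with
    ``c_base`` held fixed.  Fitted attributes: ``c_amp_``, ``c_rate_``,
    ``residual_norm_``.
    """

    def __init__(self, c_base: float = 95.0, t240_ref: float = 288.15,
                 p0: tuple[float, float] = (10.0, 0.5)):
        self.c_base = c_base
        self.t240_ref = t240_ref
        self.p0 = p0

    def fit(self, X, y):
        t240 = np.asarray(X, dtype=float).reshape(-1)
        ea = np.asarray(y, dtype=float).reshape(-1)
        if len(t240) < 3:
            raise ValueError("need at least 3 (T240, Ea) pairs")
        if np.ptp(t240) < 5.0:
            raise ValueError(
                f"T240 values must span >= 5 K, got {np.ptp(t240):.2f} K"
            )

        def model(t, amp, rate):
            return self.c_base + amp * np.exp(rate * (self.t240_ref - t))

        try:
            popt, _ = optimize.curve_fit(
                model, t240, ea, p0=self.p0,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"acclimation fit did not converge: {err}; "
                f"n={len(t240)}, T240 span {np.ptp(t240):.2f} K"
            ) from None
        self.c_amp_, self.c_rate_ = map(float, popt)
        if self.c_amp_ <= 0:
            raise ValueError(f"fitted amplitude must be positive, got {self.c_amp_}")
        self.residual_norm_ = float(np.linalg.norm(ea - model(t240, *popt)))
        return self

    def predict(self, X):
        t240 = np.asarray(X, dtype=float)
        return self.c_base + self.c_amp_ * np.exp(self.c_rate_ * (self.t240_ref - t240))


class CapacityAcclimationModel(RegressorMixin, BaseEstimator):
    """Log-linear fit of emission factor vs 10-day mean temperature.

    Model: EF(T240) = EF_ref·exp(ef_rate·(T240 − t240_ref)); OLS on
    ln EF.  Fitted attributes: ``ef_rate_``, ``ef_ref_`` (the EF at the
    reference T240, i.e. the normalisation constant), ``residual_norm_``.
    """

    def __init__(self, t240_ref: float = 288.15):
        self.t240_ref = t240_ref

    def fit(self, X, y):
        t240 = np.asarray(X, dtype=float).reshape(-1)
        ef = np.asarray(y, dtype=float).reshape(-1)
        if len(t240) < 3:
            raise ValueError("need at least 3 (T240, EF) pairs")
        if np.ptp(t240) < 5.0:
            raise ValueError(
                f"T240 values must span >= 5 K, got {np.ptp(t240):.2f} K"
            )
        if np.any(ef <= 0):
            raise ValueError("emission factors must be positive for the log fit")
        res = stats.linregress(t240 - self.t240_ref, np.log(ef))
        self.ef_rate_ = float(res.slope)
        self.ef_ref_ = float(np.exp(res.intercept))
        pred = np.log(self.ef_ref_) + self.ef_rate_ * (t240 - self.t240_ref)
        self.residual_norm_ = float(np.linalg.norm(np.log(ef) - pred))
        return self

    def predict(self, X):
        t240 = np.asarray(X, dtype=float)
        return self.ef_ref_ * np.exp(self.ef_rate_ * (t240 - self.t240_ref))


def fit_acclimation(
    pairs_ea: Sequence[tuple[float, float]],
    pairs_ef: Sequence[tuple[float, float]],
    base: float = 95.0,
    t240_ref: float = 288.15,
) -> tuple[SedgeResponseParams, dict]:
    """Recover the sedge acclimation coefficients from fitted experiments.

    ``pairs_ea``: (T240, Ea) pairs; ``pairs_ef``: (T240, EF30) pairs.
    Returns the fitted parameter set (with ``c_base`` fixed at ``base``)
    and a diagnostics dict with residual norms and the EF normalisation.
    """
    t_ea, ea = np.asarray(pairs_ea, dtype=float).T
    t_ef, ef = np.asarray(pairs_ef, dtype=float).T
    act = ActivationAcclimationModel(c_base=base, t240_ref=t240_ref).fit(t_ea, ea)
    cap = CapacityAcclimationModel(t240_ref=t240_ref).fit(t_ef, ef)
    params = SedgeResponseParams(
        c_base=base,
        c_amp=act.c_amp_,
        c_rate=act.c_rate_,
        t240_ref=t240_ref,
        ef_rate=cap.ef_rate_,
    )
    diagnostics = {
        "residual_norm_ea": act.residual_norm_,
        "residual_norm_log_ef": cap.residual_norm_,
        "ef_ref": cap.ef_ref_,
        "n_ea": len(ea),
        "n_ef": len(ef),
    }
    return params, diagnostics


def read_chamber_csv(
    steps_path,
    history_path=None,
    temp_unit: str = "C",
) -> list[ChamberExperiment]:
    """Read chamber experiments from the package CSV dialect.

    ``steps_path`` columns: experiment_id, species, step_temp,
    emission_rate, ppfd, optional blank_rate (subtracted, floored at zero
    with a warning).  ``history_path`` columns: experiment_id,
    day_offset (1..15, most recent first), daily_mean_temp.
    ``temp_unit``: "C" or "K" for all temperature columns.
    """
    if temp_unit not in ("C", "K"):
        raise ValueError("temp_unit must be 'C' or 'K'")
    offset = 273.15 if temp_unit == "C" else 0.0
    steps = pd.read_csv(steps_path)
    hist = pd.read_csv(history_path) if history_path is not None else None
    experiments = []
    for exp_id, grp in steps.groupby("experiment_id", sort=False):
        grp = grp.sort_values("step_temp")
        emission = grp["emission_rate"].to_numpy(dtype=float)
        if "blank_rate" in grp.columns and grp["blank_rate"].notna().any():
            corrected = emission - grp["blank_rate"].fillna(0.0).to_numpy(float)
            if (corrected < 0).any():
                warnings.warn(
                    f"experiment {exp_id}: blank exceeds emission at "
                    f"{(corrected < 0).sum()} step(s); flooring at zero",
                    RuntimeWarning,
                    stacklevel=2,
                )
            emission = np.clip(corrected, 0.0, None)
        prior = None
        if hist is not None:
            h = hist[hist["experiment_id"] == exp_id].sort_values("day_offset")
            if len(h):
                prior = h["daily_mean_temp"].to_numpy(dtype=float) + offset
        experiments.append(
            ChamberExperiment(
                species_label=str(grp["species"].iloc[0]),
                temps_k=grp["step_temp"].to_numpy(dtype=float) + offset,
                emissions=emission,
                ppfd=float(grp["ppfd"].iloc[0]) if "ppfd" in grp else 1000.0,
                prior_daily_means=prior,
                experiment_id=str(exp_id),
            )
        )
    return experiments
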