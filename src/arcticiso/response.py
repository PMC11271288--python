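"""Default MEGANv2.1 isoprene temperature activity and acclimation plumbing.

The short-term activity factor γ_T is a peaked function of leaf temperature
whose optimum ``T_opt`` and amplitude ``E_opt`` acclimate to the mean air
temperature of the previous 24 h (``T24``) and 240 h (``T240``):

    γ_T = E_opt · CT2·exp(CT1/R·(1/T_opt − 1/T))
                 / (CT2 − CT1·(1 − exp(CT2/R·(1/T_opt − 1/T))))

    T_opt = 313 + 0.6·(T240 − 297.15)
    E_opt = 2·exp(0.05·(T24 − 297.15))·exp(0.05·(T240 − 297.15))

with CT1 = 95 and CT2 = 230 kJ mol⁻¹.  This module also provides the
trailing-mean computation that turns a met series into (T24, T240) and the
Q10 utility used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .params import DefaultResponseParams

T_MIN_PLAUSIBLE = 200.0  # K
T_MAX_PLAUSIBLE = 330.0  # K

__all__ = [
    "TemperatureHistory",
    "trailing_means",
    "t_opt",
    "e_opt_default",
    "gamma_t_default",
    "q10",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "IrregularSamplingError",
]


class IrregularSamplingError(ValueError):
    """Raised when a met series has a sampling gap beyond tolerance."""


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


def _check_plausible(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and ((finite <= T_MIN_PLAUSIBLE) | (finite >= T_MAX_PLAUSIBLE)).any():
        raise ValueError(
            f"{name} outside plausible range ({T_MIN_PLAUSIBLE}, {T_MAX_PLAUSIBLE}) K; "
            "temperatures must be Kelvin"
        )


@dataclass(frozen=True)
class TemperatureHistory:
    """Instantaneous leaf temperature plus trailing acclimation means (K).

    ``t24``/``t240`` may be NaN during spin-up (insufficient history); all
    finite values must lie in the physically plausible band (200, 330) K.
    """

    t: float | np.ndarray
    t24: float | np.ndarray
    t240: float | np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "t24", "t240"):
            _check_plausible(name, getattr(self, name))


def trailing_means(
    series: pd.Series,
    *,
    window_hours: tuple[float, float] = (24.0, 240.0),
    gap_tolerance: pd.Timedelta | str = "0s",
) -> pd.DataFrame:
    """Trailing 24-h and 240-h means of an air-temperature series.

    Windows are left-open, right-closed on *strictly preceding* samples: the
    sample at time t does not contribute to its own mean.  The first 240 h
    (spin-up) are returned as NaN rather than computed over a shortened
    window.

    Parameters
    ----------
    series : pd.Series
        Air temperature (K) indexed by a regular DatetimeIndex.
    gap_tolerance : timedelta-like
        Maximum deviation of any sampling step from the modal step before
        the series is rejected as irregular.

    Returns
    -------
    pd.DataFrame with columns ``t24`` and ``t240``, same index as input.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must have a DatetimeIndex")
    if len(series) < 2:
        raise ValueError("need at least two samples to infer the sampling step")
    deltas = series.index.to_series().diff().dropna()
    step = deltas.mode().iloc[0]
    tol = pd.Timedelta(gap_tolerance)
    bad = deltas[(deltas - step).abs() > tol]
    if len(bad):
        first = bad.index[0]
        raise IrregularSamplingError(
            f"sampling gap of {bad.iloc[0]} at {first} exceeds tolerance "
            f"{tol} (modal step {step})"
        )
    step_hours = step / pd.Timedelta(hours=1)
    out = {}
    for name, hours in zip(("t24", "t240"), window_hours):
        n = int(round(hours / step_hours))
        if n < 1:
            raise ValueError(f"window {hours} h shorter than sampling step")
        out[name] = series.shift(1).rolling(n, min_periods=n).mean()
    return pd.DataFrame(out, index=series.index)


def t_opt(t240, params: DefaultResponseParams = DefaultResponseParams()):
    """Acclimated optimum temperature (K): 313 + 0.6·(T240 − 297.15)."""
    t240 = np.asarray(t240, dtype=float)
    return params.topt_base + params.topt_slope * (t240 - params.t_ref)


def e_opt_default(t24, t240, params: DefaultResponseParams = DefaultResponseParams()):
    """Default acclimated amplitude: 2·e^{0.05(T24−297.15)}·e^{0.05(T240−297.15)}."""
    t24 = np.asarray(t24, dtype=float)
    t240 = np.asarray(t240, dtype=float)
    return (
        params.eopt_scale
        * np.exp(params.eopt_rate24 * (t24 - params.t_ref))
        * np.exp(params.eopt_rate240 * (t240 - params.t_ref))
    )


def gamma_t_default(
    hist: TemperatureHistory,
    params: DefaultResponseParams = DefaultResponseParams(),
    *,
    eopt=None,
):
    """Default short-term temperature activity factor γ_T.

    ``eopt`` overrides the default long-term amplitude (used by the willow
    variant, which keeps this curve shape but substitutes its own E_opt).
    Returns NaN where the acclimation means are missing.
    """
    t = np.asarray(hist.t, dtype=float)
    topt = t_opt(hist.t240, params)
    if eopt is None:
        eopt = e_opt_default(hist.t24, hist.t240, params)
    x = 1.0 / topt - 1.0 / t
    num = params.ct2 * np.exp(params.ct1 / params.r_gas * x)
    den = params.ct2 - params.ct1 * (1.0 - np.exp(params.ct2 / params.r_gas * x))
    # For CT2 > CT1 > 0 the denominator is positive for all real x.
    if np.any(den[np.isfinite(den)] <= 0):
        raise AssertionError("non-positive denominator in gamma_t_default")
    return eopt * num / den


def q10(
    curve: Callable,
    t1: float = 298.15,
    t2: float = 308.15,
) -> float:
    """Q10 temperature coefficient of an emission curve.

    ``(curve(t2)/curve(t1))**(10/(t2−t1))``; reduces to the plain ratio on
    the default 25–35 °C bracket.
    """
    if not t2 > t1:
        raise ValueError(f"require t2 > t1, got {t1} and {t2}")
    e1, e2 = float(curve(t1)), float(curve(t2))
    if e1 <= 0 or e2 <= 0:
        raise ValueError(
            f"curve must be positive at both bracket ends, got {e1} and {e2}"
        )
    return (e2 / e1) ** (10.0 / (t2 - t1))
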