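"""Arctic-specific isoprene temperature responses: sedges and willows.

Sedges (Carex, Eriophorum) follow a purely exponential short-term response
whose activation energy and emission factor both acclimate to the 10-day
mean air temperature, in opposite directions:

    γ_T_sg = E_opt_sg · exp(C_sg/R · (1/303.15 − 1/T))
    C_sg      = 95 + 9.5·exp(0.53·(288.15 − T240))        [kJ mol⁻¹]
    E_opt_sg  = exp(0.12·(T240 − 288.15))

Cold-acclimated sedges are therefore far more temperature-sensitive (large
C_sg) but have smaller standard-condition emission factors — the inverse
activation-energy/emission-factor relationship observed in chamber data.
As T240 warms, C_sg relaxes to the default MEGAN activation energy of
95 kJ mol⁻¹.

Willows (boreal broadleaf deciduous shrub) keep the default peaked curve
shape but with a stronger, faster long-term amplitude response:

    E_opt_willow = 7.9 · exp(0.22·(T24 − 297.15))
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import (
    DefaultResponseParams,
    SedgeResponseParams,
    WillowCapacityParams,
)
from .response import TemperatureHistory, gamma_t_default

T_SEDGE_WARN = 313.15  # K; the exponential form is unvalidated above 40 °C

__all__ = [
    "c_sg",
    "e_opt_sg",
    "gamma_t_sedge",
    "e_opt_willow",
    "gamma_t_willow",
    "gamma_t",
    "RESPONSE_KINDS",
]


def c_sg(t240, params: SedgeResponseParams = SedgeResponseParams()):
    """Sedge activation energy (kJ mol⁻¹), decreasing in T240 toward c_base."""
    t240 = np.asarray(t240, dtype=float)
    return params.c_base + params.c_amp * np.exp(
        params.c_rate * (params.t240_ref - t240)
    )


def e_opt_sg(t240, params: SedgeResponseParams = SedgeResponseParams()):
    """Sedge acclimated emission-factor multiplier, increasing in T240."""
    t240 = np.asarray(t240, dtype=float)
    return np.exp(params.ef_rate * (t240 - params.t240_ref))


def gamma_t_sedge(
    hist: TemperatureHistory,
    params: SedgeResponseParams = SedgeResponseParams(),
):
    """Sedge short-term activity factor (no high-temperature deactivation).

    Evaluated as the published exponential for all T, but warns above
    313.15 K (40 °C) where the exponential behaviour degrades in the
    chamber data.
    """
    t = np.asarray(hist.t, dtype=float)
    if np.any(t[np.isfinite(t)] > T_SEDGE_WARN):
        warnings.warn(
            "sedge response evaluated above 313.15 K (40 °C), outside the "
            "validated exponential regime",
            RuntimeWarning,
            stacklevel=2,
        )
    c = c_sg(hist.t240, params)
    return e_opt_sg(hist.t240, params) * np.exp(
        c / params.r_gas * (1.0 / params.t_std - 1.0 / t)
    )


def e_opt_willow(t24, params: WillowCapacityParams = WillowCapacityParams()):
    """Willow acclimated amplitude: 7.9·exp(0.22·(T24 − 297.15))."""
    t24 = np.asarray(t24, dtype=float)
    return params.scale * np.exp(params.rate * (t24 - params.t24_ref))


def gamma_t_willow(
    hist: TemperatureHistory,
    default_params: DefaultResponseParams = DefaultResponseParams(),
    willow_params: WillowCapacityParams = WillowCapacityParams(),
):
    """Willow activity factor: default peaked curve with E_opt from willow."""
    return gamma_t_default(
        hist, default_params, eopt=e_opt_willow(hist.t24, willow_params)
    )


RESPONSE_KINDS = ("default", "sedge", "willow")


def gamma_t(
    kind: str,
    hist: TemperatureHistory,
    *,
    default_params: DefaultResponseParams = DefaultResponseParams(),
    sedge_params: SedgeResponseParams = SedgeResponseParams(),
    willow_params: WillowCapacityParams = WillowCapacityParams(),
):
    """Dispatch the temperature activity factor by response kind."""
    if kind == "default":
        return gamma_t_default(hist, default_params)
    if kind == "sedge":
        return gamma_t_sedge(hist, sedge_params)
    if kind == "willow":
        return gamma_t_willow(hist, default_params, willow_params)
    raise ValueError(f"unknown response kind {kind!r}; expected one of {RESPONSE_KINDS}")
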