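"""Seeded synthetic data: chamber ramp experiments and site flux series.

The generators reproduce the statistical structure the fitting code
assumes — not real instruments.  Chamber experiments are stepwise
temperature ramps whose emissions follow the sedge exponential response
for a drawn 10-day acclimation temperature, with multiplicative lognormal
noise.  Site series are half-hourly multi-week records whose temperature
combines a seasonal cycle, a diurnal cycle and an AR(1) synoptic
component, whose PPFD follows solar geometry at a configurable latitude,
and whose flux obeys the PFT-mixture model with known cover fractions
plus additive Gaussian noise.  A single integer seed drives one explicit
generator instance through all draws, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arctic import c_sg, e_opt_sg
from .chamber import ChamberExperiment
from .params import (
    ActivityFactors,
    DefaultResponseParams,
    SedgeResponseParams,
    WillowCapacityParams,
)
from .site import FluxSeries, SitePFT, model_flux

__all__ = ["SyntheticConfig", "gen_chamber", "gen_site"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults for the generators.

    Chamber: ramps 15→40 °C in 5 °C steps at PPFD ≈ 1000, 10-day mean
    temperatures drawn uniformly from a (5–18 °C) Arctic-summer band,
    5% multiplicative noise.  Site: Arctic-summer met (11 °C mean, 4 K
    diurnal and 3 K seasonal amplitudes, AR(1) synoptic anomalies) at
    68° N, sedge/willow mixture with cover fractions 0.25/0.10, leaf
    emission factors 12.0/6.5 nmol m⁻² s⁻¹, 10% additive flux noise.
    """

    seed: int = 0
    n_experiments: int = 20
    t240_range: tuple[float, float] = (278.15, 291.15)  # K
    step_temps_c: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    ef30_base: float = 12.0            # nmol m⁻² s⁻¹ at T240 = t240_ref
    chamber_noise_sd: float = 0.05     # lognormal sigma (multiplicative)
    daily_history_sd: float = 2.0      # K, spread of prior daily means
    # site met shape
    base_temp: float = 284.15          # K (11 °C summer mean)
    diurnal_amp: float = 4.0           # K
    seasonal_amp: float = 3.0          # K
    ar_coef: float = 0.85              # daily synoptic AR(1)
    ar_sd: float = 1.2                 # K
    latitude: float = 68.0             # degrees N
    ppfd_max: float = 1500.0           # µmol m⁻² s⁻¹ clear-sky noon ceiling
    lai_max: float = 1.0
    site_noise_frac: float = 0.10      # additive sd as fraction of mean flux
    true_sedge: SedgeResponseParams = SedgeResponseParams()
    true_willow: WillowCapacityParams = WillowCapacityParams()
    true_default: DefaultResponseParams = DefaultResponseParams()
    true_cover: tuple[float, float] = (0.25, 0.10)   # (sedge, willow shrub)
    leaf_efs: tuple[float, float] = (12.0, 6.5)      # nmol m⁻² s⁻¹
    factors: ActivityFactors = ActivityFactors()

    def pfts(self) -> list[SitePFT]:
        (cf_sedge, cf_shrub) = self.true_cover
        (ef_sedge, ef_shrub) = self.leaf_efs
        return [
            SitePFT("sedge", ef_sedge, "sedge", cf_sedge),
            SitePFT("willow_shrub", ef_shrub, "willow", cf_shrub),
        ]


def gen_chamber(cfg: SyntheticConfig) -> list[ChamberExperiment]:
    """Generate seeded chamber ramp experiments from the sedge response.

    Emission at each step T is
    ``ef30_base · E_opt_sg(T240) · exp(C_sg(T240)/R·(1/303.15 − 1/T))``
    times lognormal noise; the 15 prior daily means are drawn around the
    experiment's T240 and shifted so the most recent 10 average to it
    exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    sp = cfg.true_sedge
    temps_k = np.asarray(cfg.step_temps_c, dtype=float) + 273.15
    experiments = []
    for i in range(cfg.n_experiments):
        t240 = rng.uniform(*cfg.t240_range)
        c = float(c_sg(t240, sp))
        ef = cfg.ef30_base * float(e_opt_sg(t240, sp))
        clean = ef * np.exp(c / sp.r_gas * (1.0 / sp.t_std - 1.0 / temps_k))
        noise = rng.lognormal(mean=0.0, sigma=cfg.chamber_noise_sd, size=len(temps_k))
        # Daily means drawn from the population band, then the most recent
        # 10 shifted so their mean equals the drawn T240 exactly: only the
        # 10-day window is fully informative about the acclimation state.
        days = rng.uniform(*cfg.t240_range, size=15)
        days += rng.normal(0.0, cfg.daily_history_sd, size=15)
        days[:10] += t240 - days[:10].mean()
        experiments.append(
            ChamberExperiment(
                species_label="synthetic_sedge",
                temps_k=temps_k,
                emissions=clean * noise,
                ppfd=1000.0,
                prior_daily_means=days,
                experiment_id=f"synth{i:03d}",
            )
        )
    return experiments


def _ppfd_curve(index: pd.DatetimeIndex, latitude: float, ppfd_max: float) -> np.ndarray:
    """Clear-sky PPFD from solar zenith (declination + hour angle)."""
    doy = index.dayofyear.to_numpy(float)
    hour = index.hour.to_numpy(float) + index.minute.to_numpy(float) / 60.0
    decl = np.deg2rad(23.44) * np.sin(2 * np.pi * (doy - 81) / 365.25)
    lat = np.deg2rad(latitude)
    ha = np.deg2rad(15.0 * (hour - 12.0))
    cos_z = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return ppfd_max * np.clip(cos_z, 0.0, None)


def gen_site(
    cfg: SyntheticConfig,
    n_days: int = 60,
    start: str = "2021-06-01",
    heatwave: tuple[int, int, float] | None = None,
) -> tuple[FluxSeries, dict]:
    """Generate a half-hourly site record plus the generating truth.

    ``heatwave=(start_day, n_days, dT)`` adds a block temperature anomaly.
    Returns the FluxSeries (observed flux = model + noise; the first 10
    days lack acclimation and carry NaN flux) and a truth dict with the
    cover fractions, the clean flux and the noise sd.
    """
    if n_days < 20:
        raise ValueError("need n_days >= 20 to populate the 240-h acclimation")
    rng = np.random.default_rng(cfg.seed)
    index = pd.date_range(start, periods=n_days * 48, freq="30min")
    day_frac = np.arange(n_days * 48) / 48.0

    seasonal = cfg.seasonal_amp * np.sin(2 * np.pi * (day_frac - n_days / 4) / (2 * n_days))
    diurnal = cfg.diurnal_amp * np.cos(2 * np.pi * (day_frac % 1.0 - 14.0 / 24.0))
    synoptic_daily = np.empty(n_days)
    z = rng.normal(0.0, cfg.ar_sd)
    for d in range(n_days):
        z = cfg.ar_coef * z + rng.normal(0.0, cfg.ar_sd)
        synoptic_daily[d] = z
    synoptic = np.interp(day_frac, np.arange(n_days) + 0.5, synoptic_daily)
    t_air = cfg.base_temp + seasonal + diurnal + synoptic
    if heatwave is not None:
        d0, nd, dt = heatwave
        t_air[(day_frac >= d0) & (day_frac < d0 + nd)] += dt

    ppfd = _ppfd_curve(index, cfg.latitude, cfg.ppfd_max)
    lai = cfg.lai_max * (0.75 + 0.25 * np.sin(np.pi * day_frac / n_days))
    met = pd.DataFrame({"t_air": t_air, "ppfd": ppfd, "lai": lai}, index=index)
    series = FluxSeries(met)
    clean = model_flux(
        series, cfg.pfts(), cfg.factors,
        cfg.true_default, cfg.true_sedge, cfg.true_willow,
    )
    noise_sd = cfg.site_noise_frac * float(np.nanmean(clean))
    noise = rng.normal(0.0, noise_sd, size=len(clean)) if noise_sd > 0 else 0.0
    series.data["flux"] = clean + noise
    truth = {
        "cover_fractions": dict(zip(("sedge", "willow_shrub"), cfg.true_cover)),
        "clean_flux": clean,
        "noise_sd": noise_sd,
        "pfts": cfg.pfts(),
    }
    return series, truth
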