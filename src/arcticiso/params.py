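"""Parameter objects for the isoprene temperature-response models.

All energies are kJ mol⁻¹, all temperatures Kelvin, all rates K⁻¹.
Parameters are carried in explicit (frozen) dataclasses rather than being
hard-coded in the evaluators, so the same curve code serves both forward
simulation and acclimation fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

GAS_CONSTANT_KJ = 0.008314  # kJ mol⁻¹ K⁻¹
T_STANDARD = 303.15         # K, standard leaf temperature (30 °C)
T_REF_ACCLIM = 297.15       # K, reference acclimation temperature (24 °C)
ISOPRENE_MOLAR_MASS = 68.12  # g mol⁻¹


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass(frozen=True)
class DefaultResponseParams:
    """MEGANv2.1 default isoprene short-/long-term temperature response.

    ``ct1``/``ct2`` are the activation and deactivation energies of the
    peaked short-term curve; ``topt_base``/``topt_slope`` and the ``eopt_*``
    coefficients encode how the previous 24-h and 240-h mean air
    temperatures shift the curve optimum and amplitude.
    """

    ct1: float = 95.0          # kJ mol⁻¹
    ct2: float = 230.0         # kJ mol⁻¹
    r_gas: float = GAS_CONSTANT_KJ
    topt_base: float = 313.0   # K
    topt_slope: float = 0.6    # K K⁻¹
    t_ref: float = T_REF_ACCLIM
    eopt_scale: float = 2.0
    eopt_rate24: float = 0.05   # K⁻¹
    eopt_rate240: float = 0.05  # K⁻¹

    def __post_init__(self) -> None:
        if not (self.ct2 > self.ct1 > 0):
            raise ParameterError(
                f"require ct2 > ct1 > 0, got ct1={self.ct1}, ct2={self.ct2}"
            )
        if self.r_gas <= 0:
            raise ParameterError(f"gas constant must be positive, got {self.r_gas}")


@dataclass(frozen=True)
class SedgeResponseParams:
    """Sedge (Arctic grass) exponential response with acclimating parameters.

    The activation energy decays from ``c_base + c_amp`` at ``t240_ref``
    toward ``c_base`` as the 10-day mean temperature warms; the emission
    factor grows exponentially with it at rate ``ef_rate``.
    """

    c_base: float = 95.0       # kJ mol⁻¹
    c_amp: float = 9.5         # kJ mol⁻¹
    c_rate: float = 0.53       # K⁻¹
    t240_ref: float = 288.15   # K
    ef_rate: float = 0.12      # K⁻¹
    t_std: float = T_STANDARD  # K
    r_gas: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        if self.c_base <= 0 or self.c_amp <= 0:
            raise ParameterError("c_base and c_amp must be positive")
        if self.c_rate <= 0 or self.ef_rate <= 0:
            raise ParameterError("c_rate and ef_rate must be positive")


@dataclass(frozen=True)
class WillowCapacityParams:
    """Willow (boreal broadleaf deciduous shrub) acclimating emission capacity."""

    scale: float = 7.9        # dimensionless
    rate: float = 0.22        # K⁻¹
    t24_ref: float = T_REF_ACCLIM

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError(f"scale must be positive, got {self.scale}")


@dataclass(frozen=True)
class ActivityFactors:
    """Non-temperature activity factors entering the site flux model.

    ``cce`` is the MEGAN canopy factor and is applied exactly once, inside
    the leaf→canopy emission-factor scaling; ``gamma_others`` therefore
    multiplies the remaining light/age/CO₂/soil-moisture factors only
    (all default to 1; soil-moisture stress is neglected).
    """

    gamma_p: float = 1.0
    gamma_a: float = 1.0
    gamma_c: float = 1.0
    gamma_sm: float = 1.0
    cce: float = 0.3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ParameterError(f"{f.name} must be >= 0, got {v}")

    @property
    def gamma_others(self) -> float:
        return self.gamma_p * self.gamma_a * self.gamma_c * self.gamma_sm


def params_to_dict(params) -> dict:
    return asdict(params)


def params_from_dict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ParameterError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}"
        )
    return cls(**d)
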