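"""TOML configuration loading, validation and normalised dumping.

The config file carries the site description (PFT blocks) and the model
constants; unknown keys are rejected so typos fail loudly.  Example::

    [model]
    cce = 0.3
    r_gas = 0.008314
    ppfd_min = 300.0
    t_max_k = 308.15
    lai_std = 5.0

    [[pfts]]
    name = "sedge"
    leaf_ef = 12.0
    response = "sedge"
    cover_fraction = 0.25

    [sedge]                # optional parameter overrides
    c_amp = 9.5
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .params import (
    DefaultResponseParams,
    ParameterError,
    SedgeResponseParams,
    WillowCapacityParams,
    params_from_dict,
)
from .site import SitePFT

__all__ = ["Config", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Raised for schema violations or physically invalid config values."""


_MODEL_DEFAULTS = {
    "cce": 0.3,
    "r_gas": 0.008314,
    "ppfd_min": 300.0,
    "t_max_k": 308.15,
    "lai_std": 5.0,
}
_PFT_KEYS = {"name", "leaf_ef", "response", "cover_fraction"}
_TOP_KEYS = {"model", "pfts", "sedge", "willow", "default"}


@dataclass(frozen=True)
class Config:
    model: dict = field(default_factory=lambda: dict(_MODEL_DEFAULTS))
    pfts: tuple[SitePFT, ...] = ()
    sedge_params: SedgeResponseParams = SedgeResponseParams()
    willow_params: WillowCapacityParams = WillowCapacityParams()
    default_params: DefaultResponseParams = DefaultResponseParams()


def load_config(path) -> Config:
    """Load and validate a TOML config; defaults injected, unknown keys rejected."""
    raw = Path(path).read_bytes()
    try:
        doc = tomllib.loads(raw.decode("utf-8"))
    except tomllib.TOMLDecodeError as err:
        raise ConfigError(f"{path}: not valid TOML: {err}") from None

    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys: {sorted(unknown)}")

    model = dict(_MODEL_DEFAULTS)
    bad = set(doc.get("model", {})) - set(_MODEL_DEFAULTS)
    if bad:
        raise ConfigError(f"{path}: unknown [model] keys: {sorted(bad)}")
    model.update(doc.get("model", {}))
    if model["cce"] <= 0:
        raise ConfigError(f"{path}: cce must be positive, got {model['cce']}")
    if model["ppfd_min"] < 0 or model["lai_std"] <= 0 or model["r_gas"] <= 0:
        raise ConfigError(f"{path}: physically invalid [model] values")

    pfts = []
    for block in doc.get("pfts", []):
        bad = set(block) - _PFT_KEYS
        if bad:
            raise ConfigError(f"{path}: unknown [[pfts]] keys: {sorted(bad)}")
        try:
            pfts.append(
                SitePFT(
                    name=block["name"],
                    leaf_ef=block["leaf_ef"],
                    response_kind=block.get("response", "default"),
                    cover_fraction=block.get("cover_fraction"),
                )
            )
        except (KeyError, ValueError) as err:
            raise ConfigError(f"{path}: invalid [[pfts]] block: {err}") from None

    try:
        sedge = params_from_dict(
            SedgeResponseParams, doc.get("sedge", {})
        ) if doc.get("sedge") else SedgeResponseParams()
        willow = params_from_dict(
            WillowCapacityParams, doc.get("willow", {})
        ) if doc.get("willow") else WillowCapacityParams()
        default = params_from_dict(
            DefaultResponseParams, doc.get("default", {})
        ) if doc.get("default") else DefaultResponseParams()
    except ParameterError as err:
        raise ConfigError(f"{path}: {err}") from None

    return Config(model=model, pfts=tuple(pfts), sedge_params=sedge,
                  willow_params=willow, default_params=default)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(float(v)) if isinstance(v, float) else str(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def dump_config(cfg: Config) -> str:
    """Normalised TOML text; ``load(dump(load(x)))`` is a fixed point."""
    lines = ["[model]"]
    for k in sorted(_MODEL_DEFAULTS):
        lines.append(f"{k} = {_toml_value(cfg.model[k])}")
    for p in cfg.pfts:
        lines += ["", "[[pfts]]", f'name = "{p.name}"',
                  f"leaf_ef = {_toml_value(p.leaf_ef)}",
                  f'response = "{p.response_kind}"']
        if p.cover_fraction is not None:
            lines.append(f"cover_fraction = {_toml_value(p.cover_fraction)}")
    for section, params in (("sedge", cfg.sedge_params),
                            ("willow", cfg.willow_params),
                            ("default", cfg.default_params)):
        lines += ["", f"[{section}]"]
        for f in dataclasses.fields(params):
            lines.append(f"{f.name} = {_toml_value(getattr(params, f.name))}")
    return "\n".join(lines) + "\n"
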