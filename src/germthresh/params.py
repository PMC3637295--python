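"""Parameter records for the population-threshold germination models.

Each record houses the fitted constants of one model family:

* :class:`TTParams` — thermal time (TT) model: a common base temperature
  ``T_b`` and a log-normally distributed thermal-time requirement
  ``theta_T(g)``.
* :class:`MTTLowParams` — the low-temperature branch of the modified
  thermal time (MTT) model: a constant thermal time ``theta_Tm`` and a
  normally distributed minimum temperature ``T_m(g)``.
* :class:`MTTParams` — the full two-phased MTT model (low branch below
  ``T_split``, TT branch above).
* :class:`MLTParams` — maximum lifetime threshold (MLT) model: a normally
  distributed maximum potential lifetime ``p_max(g)`` and an aging time
  constant ``theta_A``.
* :class:`ATTParams` — aging thermal time (ATT) model combining thermal
  time and lifetime, optionally with a low-range extension in which the
  median lifetime declines linearly below an inflection temperature
  ``T_i``.

Units are fixed throughout the package: germination (clock) time in hours,
storage time in days, temperature in °C; hence ``theta_T`` in °C·h,
``theta_A`` in d·h and ``theta_AT`` in d·°C·h.  The spread of the
log-normal thermal time, ``sigma_lnTheta``, lives on the natural-log scale
and is dimensionless.

Records serialize to/from a small JSON dialect with explicit unit
annotations (:func:`save_params` / :func:`load_params`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

__all__ = [
    "TTParams",
    "MTTLowParams",
    "MTTParams",
    "MLTParams",
    "LowRangeExtension",
    "ATTParams",
    "ViabilityCurveParams",
    "AnyParams",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class TTParams:
    """Thermal time model constants.

    Parameters
    ----------
    theta_T50
        Median thermal time to germination, °C·h.
    T_b
        Base temperature common to all percentiles, °C.
    sigma_lnTheta
        Standard deviation of ln θ_T(g) (dimensionless, ln scale).
    """

    theta_T50: float
    T_b: float
    sigma_lnTheta: float

    def __post_init__(self) -> None:
        _require(self.theta_T50 > 0, "theta_T50 must be > 0")
        _require(self.sigma_lnTheta > 0, "sigma_lnTheta must be > 0")


@dataclass(frozen=True)
class MTTLowParams:
    """Low-temperature branch of the modified thermal time model.

    ``theta_Tm`` is the (constant) thermal time in °C·h; ``T_m50`` and
    ``sigma_Tm`` are the median and spread (°C) of the normally
    distributed minimum temperature ``T_m(g)``.
    """

    theta_Tm: float
    T_m50: float
    sigma_Tm: float

    def __post_init__(self) -> None:
        _require(self.theta_Tm > 0, "theta_Tm must be > 0")
        _require(self.sigma_Tm > 0, "sigma_Tm must be > 0")


@dataclass(frozen=True)
class MTTParams:
    """Two-phased modified thermal time model.

    Temperatures at or below ``T_split`` use the low branch (distributed
    minimum temperature); temperatures above use the TT branch.  The tie
    at ``T == T_split`` goes to the low branch by convention.
    """

    low: MTTLowParams
    high: TTParams
    T_split: float = 12.5


@dataclass(frozen=True)
class MLTParams:
    """Maximum lifetime threshold model constants.

    ``p_max50`` and ``sigma_pmax`` (both days) are the median and spread
    of the normally distributed maximum potential lifetime; ``theta_A``
    (d·h) is the aging time constant linking germination rate to the
    remaining lifetime p_max(g) − p.
    """

    p_max50: float
    sigma_pmax: float
    theta_A: float

    def __post_init__(self) -> None:
        _require(self.p_max50 > 0, "p_max50 must be > 0")
        _require(self.sigma_pmax > 0, "sigma_pmax must be > 0")
        _require(self.theta_A > 0, "theta_A must be > 0")


@dataclass(frozen=True)
class LowRangeExtension:
    """Low-range decline of the median lifetime for the ATT model.

    Below the inflection temperature ``T_i`` (°C) the median maximum
    lifetime falls linearly at rate ``k`` (d/°C) from its value
    ``p_maxi50`` (d) at ``T_i``.
    """

    k: float
    T_i: float
    p_maxi50: float

    def __post_init__(self) -> None:
        _require(self.k >= 0, "k must be >= 0")
        _require(self.p_maxi50 > 0, "p_maxi50 must be > 0")


@dataclass(frozen=True)
class ATTParams:
    """Aging thermal time model constants.

    ``theta_AT`` (d·°C·h) is the aging thermal time, ``T_b`` the base
    temperature, and ``p_max50``/``sigma_pmax`` (days) the median and
    spread of the maximum potential lifetime.  With a
    :class:`LowRangeExtension` present, predictions below ``T_i`` use the
    linearly declining median lifetime.
    """

    p_max50: float
    sigma_pmax: float
    theta_AT: float
    T_b: float
    low_range_extension: Optional[LowRangeExtension] = None

    def __post_init__(self) -> None:
        _require(self.p_max50 > 0, "p_max50 must be > 0")
        _require(self.sigma_pmax > 0, "sigma_pmax must be > 0")
        _require(self.theta_AT > 0, "theta_AT must be > 0")
        if self.low_range_extension is not None:
            _require(
                self.T_b < self.low_range_extension.T_i,
                "T_b must lie below the inflection temperature T_i",
            )


@dataclass(frozen=True)
class ViabilityCurveParams:
    """Normal-CDF viability-loss curve: viability = Φ((mu − p)/sigma)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        _require(self.sigma > 0, "sigma must be > 0")


AnyParams = Union[TTParams, MTTLowParams, MTTParams, MLTParams, ATTParams]

# ---------------------------------------------------------------------------
# JSON (de)serialization

_UNITS = {
    "theta_T50": "degC*h",
    "T_b": "degC",
    "sigma_lnTheta": "ln scale (dimensionless)",
    "theta_Tm": "degC*h",
    "T_m50": "degC",
    "sigma_Tm": "degC",
    "T_split": "degC",
    "p_max50": "d",
    "sigma_pmax": "d",
    "theta_A": "d*h",
    "theta_AT": "d*degC*h",
    "k": "d/degC",
    "T_i": "degC",
    "p_maxi50": "d",
    "mu": "d",
    "sigma": "d",
}

_MODEL_TAGS = {
    TTParams: "tt",
    MTTLowParams: "mtt_low",
    MTTParams: "mtt",
    MLTParams: "mlt",
    ATTParams: "att",
    ViabilityCurveParams: "viability",
}


def params_to_dict(params) -> dict:
    """Convert a parameter record to a plain dict with unit annotations."""
    tag = _MODEL_TAGS.get(type(params))
    if tag is None:
        raise TypeError(f"not a parameter record: {type(params).__name__}")
    if isinstance(params, MTTParams):
        return {
            "model": "mtt",
            "T_split": params.T_split,
            "low": params_to_dict(params.low),
            "high": params_to_dict(params.high),
            "units": {"T_split": _UNITS["T_split"]},
        }
    out = {"model": tag}
    fields = {
        k: v for k, v in params.__dict__.items() if k != "low_range_extension"
    }
    out.update(fields)
    if isinstance(params, ATTParams) and params.low_range_extension is not None:
        ext = params.low_range_extension
        out["low_range_extension"] = {
            "k": ext.k, "T_i": ext.T_i, "p_maxi50": ext.p_maxi50,
        }
    out["units"] = {k: _UNITS[k] for k in fields}
    return out


def params_from_dict(d: dict):
    """Rebuild a parameter record from :func:`params_to_dict` output."""
    d = dict(d)
    d.pop("units", None)
    tag = d.pop("model", None)
    if tag == "tt":
        return TTParams(**d)
    if tag == "mtt_low":
        return MTTLowParams(**d)
    if tag == "mtt":
        return MTTParams(
            low=params_from_dict(d["low"]),
            high=params_from_dict(d["high"]),
            T_split=d.get("T_split", 12.5),
        )
    if tag == "mlt":
        return MLTParams(**d)
    if tag == "att":
        ext = d.pop("low_range_extension", None)
        if ext is not None:
            ext = LowRangeExtension(**ext)
        return ATTParams(low_range_extension=ext, **d)
    if tag == "viability":
        return ViabilityCurveParams(**d)
    raise ValueError(f"unknown model tag: {tag!r}")


def save_params(params, path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=2) + "\n")


def load_params(path):
    return params_from_dict(json.loads(Path(path).read_text()))
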