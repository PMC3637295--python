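"""Forward mathematics of the population-threshold germination models.

Every model treats the seed lot as a population indexed by a germination
percentile ``g`` in (0, 1): the fraction ``g`` of seeds that germinates
earliest.  A model assigns each percentile a threshold (thermal time,
minimum temperature or maximum lifetime) drawn from a normal or
log-normal distribution, and the cumulative germination fraction at any
condition is the probability that a seed's threshold has been exceeded:

* thermal time (TT):      g = Φ( [ln((T − T_b)·t) − ln θ_T(50)] / σ_lnθ )
* modified TT, low range: g = Φ( [T − θ_Tm/t − T_m(50)] / σ_Tm )
* maximum lifetime (MLT): g = Φ( [p_max(50) − p − θ_A/t] / σ_pmax )
* aging thermal time:     g = Φ( [p_max(50) − p − θ_AT/((T − T_b)·t)] / σ_pmax )

with Φ the standard normal CDF, T the germination temperature (°C), t the
time since imbibition (h) and p the storage (aging) time (d).  The ATT
low-range extension replaces the median lifetime by
p_maxi(50) − k·(T_i − T) below the inflection temperature T_i.

The probit convention is the plain standard-normal quantile (no historical
+5 offset).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .params import (
    ATTParams,
    MLTParams,
    MTTLowParams,
    MTTParams,
    TTParams,
)

__all__ = [
    "probit",
    "inverse_probit",
    "predict_fraction_tt",
    "predict_fraction_mtt_low",
    "predict_fraction_mtt",
    "predict_fraction_mlt",
    "predict_fraction_att",
    "predict_fraction",
    "time_to_percentile",
    "pmax_quantile",
    "theta_T_quantile",
    "normalize_storage_time",
    "normalized_thermal_time",
]


def _maybe_scalar(x, *inputs):
    """Return a python float when every input was scalar."""
    if all(np.ndim(v) == 0 for v in inputs):
        return float(x)
    return x


def probit(g):
    """Standard-normal quantile of a germination fraction.

    Raises ``ValueError`` outside the open interval (0, 1); the endpoints
    map to ±∞ and carry no probit value.
    """
    g_arr = np.asarray(g, dtype=float)
    if np.any(g_arr <= 0.0) or np.any(g_arr >= 1.0):
        raise ValueError("probit requires 0 < g < 1")
    return _maybe_scalar(norm.ppf(g_arr), g)


def inverse_probit(z):
    """Standard normal CDF: maps a probit z-score back to a fraction."""
    return _maybe_scalar(norm.cdf(np.asarray(z, dtype=float)), z)


# ---------------------------------------------------------------------------
# cumulative-fraction predictions


def predict_fraction_tt(params: TTParams, T, t):
    """Cumulative germinated fraction under the thermal time model.

    Zero below the base temperature; otherwise Φ applied to the log
    thermal-time excess.  ``T`` and ``t`` broadcast.
    """
    T_arr, t_arr = np.broadcast_arrays(
        np.asarray(T, dtype=float), np.asarray(t, dtype=float)
    )
    if np.any(t_arr <= 0):
        raise ValueError("time t must be > 0")
    accum = np.clip(T_arr - params.T_b, 0.0, None) * t_arr
    with np.errstate(divide="ignore"):
        z = (np.log(accum) - np.log(params.theta_T50)) / params.sigma_lnTheta
    frac = np.where(accum > 0, norm.cdf(z), 0.0)
    return _maybe_scalar(frac, T, t)


def predict_fraction_mtt_low(params: MTTLowParams, T, t):
    """Cumulative fraction under the low-range (minimum temperature) branch.

    As t → ∞ the fraction saturates at Φ((T − T_m(50))/σ_Tm): seeds whose
    minimum temperature lies above ``T`` never germinate there.
    """
    T_arr, t_arr = np.broadcast_arrays(
        np.asarray(T, dtype=float), np.asarray(t, dtype=float)
    )
    if np.any(t_arr <= 0):
        raise ValueError("time t must be > 0")
    z = (T_arr - params.theta_Tm / t_arr - params.T_m50) / params.sigma_Tm
    return _maybe_scalar(norm.cdf(z), T, t)


def predict_fraction_mtt(params: MTTParams, T, t):
    """Two-phased dispatch: low branch for T ≤ T_split, TT branch above."""
    T_arr, t_arr = np.broadcast_arrays(
        np.asarray(T, dtype=float), np.asarray(t, dtype=float)
    )
    low = predict_fraction_mtt_low(params.low, T_arr, t_arr)
    high = predict_fraction_tt(params.high, T_arr, t_arr)
    frac = np.where(T_arr <= params.T_split, low, high)
    return _maybe_scalar(frac, T, t)


def predict_fraction_mlt(params: MLTParams, p, t):
    """Cumulative fraction under the maximum lifetime threshold model.

    ``p`` is the storage (aging) time in days.  The limiting fraction as
    t → ∞ is Φ((p_max(50) − p)/σ_pmax): seeds whose lifetime was exceeded
    in storage are dead.
    """
    p_arr, t_arr = np.broadcast_arrays(
        np.asarray(p, dtype=float), np.asarray(t, dtype=float)
    )
    if np.any(t_arr <= 0):
        raise ValueError("time t must be > 0")
    if np.any(p_arr < 0):
        raise ValueError("storage time p must be >= 0")
    z = (params.p_max50 - p_arr - params.theta_A / t_arr) / params.sigma_pmax
    return _maybe_scalar(norm.cdf(z), p, t)


def _att_median_pmax(params: ATTParams, T_arr: np.ndarray) -> np.ndarray:
    """Median maximum lifetime, with the low-range decline when present."""
    ext = params.low_range_extension
    if ext is None:
        return np.full_like(T_arr, params.p_max50)
    low_median = ext.p_maxi50 - ext.k * (ext.T_i - T_arr)
    return np.where(T_arr < ext.T_i, low_median, params.p_max50)


def predict_fraction_att(params: ATTParams, T, p, t):
    """Cumulative fraction under the aging thermal time model.

    Combines temperature and storage through the aging thermal time
    θ_AT = (T − T_b)·(p_max(g) − p)·t_g.  Below the inflection
    temperature of a low-range extension, the median lifetime declines
    linearly with temperature.  ``T ≤ T_b`` is a domain error (the model
    accumulates no thermal time there).
    """
    T_arr, p_arr, t_arr = np.broadcast_arrays(
        np.asarray(T, dtype=float),
        np.asarray(p, dtype=float),
        np.asarray(t, dtype=float),
    )
    if np.any(t_arr <= 0):
        raise ValueError("time t must be > 0")
    if np.any(p_arr < 0):
        raise ValueError("storage time p must be >= 0")
    if np.any(T_arr <= params.T_b):
        raise ValueError("temperature must exceed the base temperature T_b")
    median = _att_median_pmax(params, T_arr)
    z = (median - p_arr - params.theta_AT / ((T_arr - params.T_b) * t_arr))
    z = z / params.sigma_pmax
    return _maybe_scalar(norm.cdf(z), T, p, t)


def predict_fraction(params, T=None, p=None, t=None):
    """Dispatch to the appropriate ``predict_fraction_*`` by parameter type.

    ``T`` is ignored by the MLT model and ``p`` by the thermal models.
    """
    if isinstance(params, TTParams):
        return predict_fraction_tt(params, T, t)
    if isinstance(params, MTTLowParams):
        return predict_fraction_mtt_low(params, T, t)
    if isinstance(params, MTTParams):
        return predict_fraction_mtt(params, T, t)
    if isinstance(params, MLTParams):
        return predict_fraction_mlt(params, 0.0 if p is None else p, t)
    if isinstance(params, ATTParams):
        return predict_fraction_att(params, T, 0.0 if p is None else p, t)
    raise TypeError(f"unsupported parameter record: {type(params).__name__}")


# ---------------------------------------------------------------------------
# quantiles and inverse (time) predictions


def theta_T_quantile(params: TTParams, g):
    """Thermal time θ_T(g) of percentile g (log-normal quantile), °C·h."""
    z = probit(g)
    return np.exp(np.log(params.theta_T50) + params.sigma_lnTheta * np.asarray(z))


def pmax_quantile(params, g):
    """Maximum potential lifetime p_max(g) of percentile g, days.

    Earlier-germinating percentiles carry the larger lifetimes, so the
    quantile runs downhill in g: p_max(g) = p_max(50) − σ_pmax·probit(g).
    Accepts MLT or ATT parameter records.
    """
    if not isinstance(params, (MLTParams, ATTParams)):
        raise TypeError("pmax_quantile needs MLT or ATT parameters")
    z = np.asarray(probit(g))
    out = params.p_max50 - params.sigma_pmax * z
    return _maybe_scalar(out, g)


def _att_median_pmax_scalar(params: ATTParams, T: float) -> float:
    return float(_att_median_pmax(params, np.asarray([float(T)]))[0])


def time_to_percentile(params, g, T=None, p=0.0):
    """Germination time t_g (h) of percentile g, or ``inf`` if unreachable.

    Inverts the model's probit equation in closed form.  A percentile
    beyond the limiting fraction of the treatment (e.g. a dead seed
    fraction after long storage, or a cold-blocked fraction in the MTT
    low range) has no finite germination time and returns ``inf``.
    """
    z = probit(g)
    if isinstance(params, TTParams):
        if T is None:
            raise ValueError("TT model needs a temperature")
        if T <= params.T_b:
            return float("inf")
        return float(theta_T_quantile(params, g) / (T - params.T_b))
    if isinstance(params, MTTLowParams):
        if T is None:
            raise ValueError("MTT low branch needs a temperature")
        denom = T - params.T_m50 - params.sigma_Tm * z
        if denom <= 0:
            return float("inf")
        return float(params.theta_Tm / denom)
    if isinstance(params, MTTParams):
        branch = params.low if T <= params.T_split else params.high
        return time_to_percentile(branch, g, T=T, p=p)
    if isinstance(params, MLTParams):
        denom = params.p_max50 - p - params.sigma_pmax * z
        if denom <= 0:
            return float("inf")
        return float(params.theta_A / denom)
    if isinstance(params, ATTParams):
        if T is None:
            raise ValueError("ATT model needs a temperature")
        if T <= params.T_b:
            raise ValueError("temperature must exceed the base temperature T_b")
        median = _att_median_pmax_scalar(params, T)
        denom = median - p - params.sigma_pmax * z
        if denom <= 0:
            return float("inf")
        return float(params.theta_AT / ((T - params.T_b) * denom))
    raise TypeError(f"unsupported parameter record: {type(params).__name__}")


# ---------------------------------------------------------------------------
# normalization transforms


def normalize_storage_time(t_g, p, p_max_g):
    """Map a stored-seed germination time onto the control time course.

    Multiplies the observed time by (1 − p/p_max(g)).  For times that
    follow the MLT model exactly this returns the control (p = 0) time of
    the same percentile, θ_A/p_max(g), whatever the storage time — the
    collapse that validates the fitted lifetime distribution.
    """
    t_arr, p_arr, pm_arr = np.broadcast_arrays(
        np.asarray(t_g, dtype=float),
        np.asarray(p, dtype=float),
        np.asarray(p_max_g, dtype=float),
    )
    if np.any(p_arr >= pm_arr):
        raise ValueError("seed fraction dead: storage p >= its lifetime p_max(g)")
    out = (1.0 - p_arr / pm_arr) * t_arr
    return _maybe_scalar(out, t_g, p, p_max_g)


def normalized_thermal_time(params: ATTParams, T, p, t_g, g):
    """Normalized thermal time θ_NT (°C·h) of one germination observation.

    High range (no extension, or T ≥ T_i):
        θ_NT = (T − T_b)·(1 − p/p_max(g))·t_g
    Low range (extension present, T < T_i): storage and chilling age
    interchangeably, so the effective aging is p + k·(T_i − T) and the
    lifetime quantile is taken from p_maxi(g):
        θ_NT = (T − T_b)·(1 − [p + k·(T_i − T)]/p_maxi(g))·t_g
    (equivalently: normalize to the control course at T_i, then multiply
    by T_i − T_b).

    For exact ATT-model times this equals θ_AT/p_max(g) — independent of
    temperature and storage — so all treatments collapse to one curve in
    g versus θ_NT.
    """
    T = float(T)
    p = float(p)
    if T <= params.T_b:
        raise ValueError("temperature must exceed the base temperature T_b")
    if p < 0:
        raise ValueError("storage time p must be >= 0")
    z = probit(g)
    ext = params.low_range_extension
    if ext is not None and T < ext.T_i:
        p_eff = p + ext.k * (ext.T_i - T)
        pmax_g = ext.p_maxi50 - params.sigma_pmax * z
    else:
        p_eff = p
        pmax_g = params.p_max50 - params.sigma_pmax * z
    if p_eff >= pmax_g:
        raise ValueError("seed fraction dead: effective aging >= lifetime")
    return float((T - params.T_b) * (1.0 - p_eff / pmax_g) * np.asarray(t_g))
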