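"""Parameter estimation for the threshold germination models.

All models are fit by least squares on the probit scale: each retained
observation contributes a response probit(cumulative fraction germinated)
and the model supplies the matching z-score.  Every model here is linear
in its coefficients once the single genuinely nonlinear parameter (the
base temperature ``T_b``) is held fixed, so fitting profiles an exact
ordinary-least-squares solve over a 1-D search on ``T_b`` — a coarse grid
to bracket the optimum, then a bounded scalar minimization to refine it.
This is exact where a generic damped Gauss–Newton iteration would be
approximate, and it cannot diverge.

Data preparation follows the source experiment's rules: percentile
germination times are read off cumulative curves by linear interpolation
(:func:`percentile_times`), and the final 5 % of germination of each
treatment is excluded before regression (:func:`censor_final_five_percent`),
as are fractions of exactly 0 or 1, whose probit is undefined.

Goodness of fit is reported as adjusted R² (probit scale), the
replicate-weighted RMSE, and a Gaussian least-squares AIC
(N·ln(RSS/N) + 2k, constant terms dropped — only AIC differences are
meaningful).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar
from scipy.stats import norm

from .params import (
    ATTParams,
    LowRangeExtension,
    MLTParams,
    MTTLowParams,
    MTTParams,
    TTParams,
    ViabilityCurveParams,
)

__all__ = [
    "NonIdentifiableError",
    "FitResult",
    "GRLinesFit",
    "percentile_times",
    "percentile_times_table",
    "censor_final_five_percent",
    "pool_replicates",
    "drop_repeated_counts",
    "regression_points",
    "normalize_max_germination",
    "goodness",
    "combined_aic",
    "fit_tt",
    "fit_mtt",
    "fit_mlt",
    "fit_att_one_phase",
    "fit_att_two_phase",
    "fit_gr_lines",
    "regress_inv_thetaA",
    "fit_viability_normal",
]

TREATMENT_COLS = ["temperature_C", "storage_days"]
SERIES_COLS = TREATMENT_COLS + ["replicate"]


class NonIdentifiableError(ValueError):
    """The requested fit has no unique solution on the given data."""


@dataclass
class FitResult:
    """Fitted parameters plus probit-scale goodness-of-fit diagnostics."""

    params: object
    r2: float
    adjusted_r2: float
    rmse: float
    aic: float
    n_obs: int
    k_params: int
    converged: bool
    residuals: np.ndarray = field(repr=False)
    flags: tuple = ()


# ---------------------------------------------------------------------------
# data preparation


def percentile_times(times, cum_pct, targets=(10, 30, 50, 70)):
    """Times to reach target germination percentages, by linear interpolation.

    ``times``/``cum_pct`` describe one cumulative series (sorted by time,
    percentages nondecreasing); an implicit origin (t=0, 0 %) starts the
    curve.  A target met exactly at an observation takes that (first)
    observation's time; a target the series never reaches maps to NaN.
    Returns ``{target: time or nan}``.
    """
    t = np.asarray(times, dtype=float)
    pct = np.asarray(cum_pct, dtype=float)
    if t.size == 0:
        raise ValueError("empty germination series")
    if np.any(np.diff(t) < 0) or np.any(np.diff(pct) < -1e-9):
        raise ValueError("series must be sorted by time with nondecreasing percentages")
    out = {}
    for target in targets:
        idx = np.nonzero(pct >= target - 1e-12)[0]
        if idx.size == 0:
            out[target] = float("nan")
            continue
        i = int(idx[0])
        if abs(pct[i] - target) <= 1e-12:
            out[target] = float(t[i])
            continue
        t0, p0 = (t[i - 1], pct[i - 1]) if i > 0 else (0.0, 0.0)
        out[target] = float(t0 + (target - p0) * (t[i] - t0) / (pct[i] - p0))
    return out


def percentile_times_table(obs: pd.DataFrame, targets=(10, 30, 50, 70)) -> pd.DataFrame:
    """Interpolated percentile times for every (temperature, storage, replicate).

    Long format: temperature_C, storage_days, replicate, percent, time_h.
    Unreached targets are omitted.
    """
    rows = []
    for key, grp in obs.groupby(SERIES_COLS, sort=True):
        grp = grp.sort_values("time_h")
        pct = 100.0 * grp["n_germ_cum"].to_numpy() / grp["n_sown"].to_numpy()
        tg = percentile_times(grp["time_h"].to_numpy(), pct, targets)
        for target, t in tg.items():
            if math.isfinite(t):
                rows.append(dict(zip(SERIES_COLS, key), percent=target, time_h=t))
    return pd.DataFrame(rows, columns=SERIES_COLS + ["percent", "time_h"])


def censor_final_five_percent(obs: pd.DataFrame) -> pd.DataFrame:
    """Drop the final 5 % of germination of each treatment, and 0/1 fractions.

    Within each (temperature, storage) treatment, observations whose
    cumulative percentage exceeds (plateau − 5 points) are removed, where
    the plateau is the treatment's final cumulative percentage.  For tiny
    plateaus the cut never reaches below half the plateau.  Fractions of
    exactly 0 or 1 are always removed (probit undefined).
    """
    pct = 100.0 * obs["n_germ_cum"].to_numpy() / obs["n_sown"].to_numpy()
    obs = obs.assign(_pct=pct)
    kept = []
    for _, grp in obs.groupby(TREATMENT_COLS, sort=False):
        plateau = grp["_pct"].max()
        cut = max(plateau - 5.0, 0.5 * plateau)
        keep = (grp["_pct"] <= cut + 1e-9) & (grp["_pct"] > 0) & (grp["_pct"] < 100)
        kept.append(grp.loc[keep])
    out = pd.concat(kept) if kept else obs.iloc[:0]
    return out.drop(columns="_pct").reset_index(drop=True)


def pool_replicates(obs: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate counts per treatment × recording time.

    Probit of a 150-seed pooled fraction is far less noisy (and less
    Jensen-biased) than three 50-seed probits; the source analysis pooled
    replicates the same way.
    """
    out = obs.groupby(TREATMENT_COLS + ["time_h"], as_index=False).agg(
        n_sown=("n_sown", "sum"), n_germ_cum=("n_germ_cum", "sum"))
    out["replicate"] = "pooled"
    return out[TREATMENT_COLS + ["time_h", "replicate", "n_sown", "n_germ_cum"]]


def drop_repeated_counts(obs: pd.DataFrame) -> pd.DataFrame:
    """Keep only recordings where the cumulative count changed.

    A count unchanged since the previous recording re-states the same
    seeds and carries no new information; on noisy step curves the
    hundreds of repeated plateau rows otherwise anchor the censored
    plateau and bias θ and p_max(50) estimates downward.
    """
    kept = []
    for _, grp in obs.groupby(SERIES_COLS, sort=False):
        grp = grp.sort_values("time_h")
        changed = grp["n_germ_cum"].diff().fillna(1.0).ne(0)
        kept.append(grp[changed])
    out = pd.concat(kept) if kept else obs.iloc[:0]
    return out.reset_index(drop=True)


def regression_points(obs: pd.DataFrame, pool: bool = True,
                      drop_repeats: bool = True, censor: bool = True) -> pd.DataFrame:
    """Standard data preparation ahead of a probit-scale fit.

    Pools replicates, drops repeated counts, then applies the final-5 %
    censor and the 0/1-fraction exclusion.  Each step can be disabled.
    """
    out = obs
    if pool:
        out = pool_replicates(out)
    if drop_repeats:
        out = drop_repeated_counts(out)
    if censor:
        out = censor_final_five_percent(out)
    return out


def normalize_max_germination(obs: pd.DataFrame) -> pd.DataFrame:
    """Rescale cumulative fractions by each temperature's maximum germination.

    Divides every cumulative fraction at a temperature by the maximum
    final fraction observed at that temperature (across storage times and
    replicates), so control plateaus become 1.0.  Returns a copy with
    float ``n_germ_cum``.
    """
    out = obs.copy()
    frac = out["n_germ_cum"].to_numpy(dtype=float) / out["n_sown"].to_numpy()
    scale = pd.Series(frac, index=out.index).groupby(out["temperature_C"]).transform("max")
    if (scale <= 0).any():
        raise ValueError("a temperature group has zero germination; cannot rescale")
    out["n_germ_cum"] = frac / scale.to_numpy() * out["n_sown"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# goodness of fit


def goodness(observed, predicted, k_params, groups=None):
    """Probit-scale goodness statistics: adjusted R², RMSE, AIC.

    RMSE is replicate-weighted: with ``groups`` labelling treatments,
    RMSE = sqrt(Σ_i n_i (x_i − ȳ_i)² / N) with x_i the (group-constant)
    prediction and ȳ_i the group mean of the observations; without
    groups each point is its own treatment and this is the ordinary
    residual RMSE.  AIC is the Gaussian least-squares form
    N·ln(RSS/N) + 2k with constants dropped.
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if y.shape != x.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    if n <= k_params + 1:
        raise ValueError("adjusted R^2 undefined: need n_obs > k_params + 1")
    resid = y - x
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_params - 1)
    if groups is None:
        rmse = math.sqrt(rss / n)
    else:
        codes, _ = pd.factorize(pd.Series(list(groups)))
        df = pd.DataFrame({"y": y, "x": x, "g": codes})
        agg = df.groupby("g", sort=False).agg(n=("y", "size"), ym=("y", "mean"), xm=("x", "mean"))
        rmse = math.sqrt(float((agg["n"] * (agg["xm"] - agg["ym"]) ** 2).sum()) / n)
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * k_params
    return {"r2": r2, "adjusted_r2": adj, "rmse": rmse, "aic": aic,
            "rss": rss, "n_obs": n, "k_params": k_params}


def combined_aic(fits: Sequence[FitResult]) -> float:
    """AIC of several independently fitted partitions treated as one model."""
    rss = sum(float(f.residuals @ f.residuals) for f in fits)
    n = sum(f.n_obs for f in fits)
    k = sum(f.k_params for f in fits)
    return n * math.log(max(rss, 1e-300) / n) + 2 * k


# ---------------------------------------------------------------------------
# probit-scale regression machinery


def _probit_response(obs: pd.DataFrame):
    frac = obs["n_germ_cum"].to_numpy(dtype=float) / obs["n_sown"].to_numpy()
    if np.any(frac <= 0) or np.any(frac >= 1):
        raise ValueError(
            "fractions of exactly 0 or 1 present; apply censor_final_five_percent first"
        )
    return norm.ppf(frac)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares solve returning (coefficients, RSS); raises if singular."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NonIdentifiableError("singular design: parameters confounded on these data")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _profile_Tb(sse: Callable[[float], float], hi: float, lo: Optional[float] = None,
                n_grid: int = 81) -> float:
    """Minimize a smooth 1-D SSE profile over T_b in (lo, hi)."""
    if lo is None:
        lo = hi - 50.0
    grid = np.linspace(lo, hi - 1e-6, n_grid)
    vals = np.array([sse(Tb) for Tb in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(sse, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x) if res.fun <= vals[i] else float(grid[i])


def _treatment_groups(obs: pd.DataFrame):
    return list(zip(obs["temperature_C"], obs["storage_days"], obs["time_h"]))


def _make_result(params, y, yhat, k, obs, converged=True, flags=()) -> FitResult:
    g = goodness(y, yhat, k, groups=_treatment_groups(obs))
    return FitResult(params=params, r2=g["r2"], adjusted_r2=g["adjusted_r2"],
                     rmse=g["rmse"], aic=g["aic"], n_obs=g["n_obs"], k_params=k,
                     converged=converged, residuals=np.asarray(y) - np.asarray(yhat),
                     flags=tuple(flags))


# ---------------------------------------------------------------------------
# model fits


def fit_tt(obs: pd.DataFrame) -> FitResult:
    """Fit the thermal time model by probit-scale profiled least squares.

    On the probit scale the TT model is z = [ln((T−T_b)t) − ln θ_T(50)]/σ,
    linear in (1/σ, ln θ_T(50)/σ) for fixed T_b; T_b is profiled.
    Requires at least two distinct temperatures (one leaves T_b
    unidentifiable).
    """
    y = _probit_response(obs)
    T = obs["temperature_C"].to_numpy(dtype=float)
    t = obs["time_h"].to_numpy(dtype=float)
    if np.unique(T).size < 2:
        raise NonIdentifiableError("T_b unidentifiable: need >= 2 distinct temperatures")
    T_max = float(T.min())

    def design(Tb):
        x = np.log((T - Tb) * t)
        return np.column_stack([np.ones_like(x), x])

    def sse(Tb):
        try:
            _, rss = _ols(design(Tb), y)
        except NonIdentifiableError:
            return float("inf")
        return rss

    Tb = _profile_Tb(sse, T_max)
    coef, _ = _ols(design(Tb), y)
    alpha, beta = coef
    flags = []
    if beta <= 0:
        raise NonIdentifiableError("germination does not accumulate with thermal time")
    sigma = 1.0 / beta
    theta50 = math.exp(-alpha / beta)
    params = TTParams(theta_T50=theta50, T_b=Tb, sigma_lnTheta=sigma)
    yhat = design(Tb) @ coef
    if Tb <= T_max - 49.9:
        flags.append("T_b at search boundary")
    return _make_result(params, y, yhat, 3, obs, flags=flags)


def _fit_mtt_low(obs: pd.DataFrame) -> FitResult:
    """Low-range MTT branch: z = [T − θ_Tm/t − T_m(50)]/σ_Tm, fully linear."""
    y = _probit_response(obs)
    T = obs["temperature_C"].to_numpy(dtype=float)
    t = obs["time_h"].to_numpy(dtype=float)
    if np.unique(T).size < 2:
        raise NonIdentifiableError("MTT low branch needs >= 2 distinct temperatures")
    X = np.column_stack([np.ones_like(T), T, 1.0 / t])
    coef, _ = _ols(X, y)
    c0, c1, c2 = coef
    if c1 <= 0:
        raise NonIdentifiableError("germination does not increase with temperature")
    sigma = 1.0 / c1
    params = MTTLowParams(theta_Tm=-c2 / c1, T_m50=-c0 / c1, sigma_Tm=sigma)
    return _make_result(params, y, X @ coef, 3, obs)


def fit_mtt(obs: pd.DataFrame, T_split: float = 12.5) -> tuple[FitResult, FitResult]:
    """Fit the two-phased MTT model: low branch at T ≤ T_split, TT above.

    The two partitions are fit independently; returns (low, high) fit
    results.  Use :func:`combined_aic` to compare the pair against a
    single TT fit of the same observations.
    """
    low = obs[obs["temperature_C"] <= T_split]
    high = obs[obs["temperature_C"] > T_split]
    if low.empty or high.empty:
        raise NonIdentifiableError("T_split leaves an empty temperature partition")
    return _fit_mtt_low(low), fit_tt(high)


def fit_mlt(obs: pd.DataFrame) -> FitResult:
    """Fit the maximum lifetime threshold model at one temperature.

    z = [p_max(50) − p − θ_A/t]/σ_pmax is linear in its three
    coefficients.  Needs at least two distinct storage times (with only
    one, p_max(50) and θ_A are confounded through the intercept).
    """
    y = _probit_response(obs)
    p = obs["storage_days"].to_numpy(dtype=float)
    t = obs["time_h"].to_numpy(dtype=float)
    if np.unique(p).size < 2:
        raise NonIdentifiableError(
            "p_max(50) and theta_A confounded: need >= 2 distinct storage times"
        )
    X = np.column_stack([np.ones_like(p), p, 1.0 / t])
    coef, _ = _ols(X, y)
    c0, c1, c2 = coef
    if c1 >= 0:
        raise NonIdentifiableError("germination does not decline with storage time")
    sigma = -1.0 / c1
    params = MLTParams(p_max50=c0 * sigma, sigma_pmax=sigma, theta_A=-c2 * sigma)
    return _make_result(params, y, X @ coef, 3, obs)


def fit_att_one_phase(obs: pd.DataFrame) -> FitResult:
    """Fit the ATT model jointly over all temperatures and storage times.

    z = [p_max(50) − p − θ_AT/((T−T_b)t)]/σ_pmax; linear for fixed T_b,
    which is profiled.  Needs ≥ 2 distinct temperatures (else T_b and
    θ_AT are confounded) and ≥ 2 distinct storage times.
    """
    y = _probit_response(obs)
    T = obs["temperature_C"].to_numpy(dtype=float)
    p = obs["storage_days"].to_numpy(dtype=float)
    t = obs["time_h"].to_numpy(dtype=float)
    if np.unique(T).size < 2:
        raise NonIdentifiableError("T_b and theta_AT confounded: need >= 2 temperatures")
    if np.unique(p).size < 2:
        raise NonIdentifiableError("need >= 2 distinct storage times")
    T_max = float(T.min())

    def design(Tb):
        return np.column_stack([np.ones_like(p), p, 1.0 / ((T - Tb) * t)])

    def sse(Tb):
        try:
            _, rss = _ols(design(Tb), y)
        except NonIdentifiableError:
            return float("inf")
        return rss

    Tb = _profile_Tb(sse, T_max)
    coef, _ = _ols(design(Tb), y)
    c0, c1, c2 = coef
    if c1 >= 0:
        raise NonIdentifiableError("germination does not decline with storage time")
    sigma = -1.0 / c1
    params = ATTParams(p_max50=c0 * sigma, sigma_pmax=sigma,
                       theta_AT=-c2 * sigma, T_b=Tb)
    return _make_result(params, y, design(Tb) @ coef, 4, obs)


def fit_att_two_phase(obs: pd.DataFrame, T_split: float = 12.5,
                      fix_k: Optional[float] = None) -> tuple[FitResult, FitResult]:
    """Fit the two-phased ATT model; returns (low, high) fit results.

    The high partition (T > T_split) is fit with the plain ATT equation.
    The low partition adds the linear decline of the median lifetime,
    z = [p_maxi(50) − k(T_i − T) − p − θ_AT/((T−T_b)t)]/σ_pmax.  Since
    p_maxi(50) and k·T_i enter only through their difference, p_maxi(50)
    is anchored to the high-range p_max(50) estimate and T_i solved from
    the coefficients, then constrained to the gap between the two
    temperature partitions (clamped and flagged at a boundary, with
    p_maxi(50) re-derived).  ``fix_k=0`` drops the decline term, reducing
    the low fit exactly to :func:`fit_att_one_phase` on that partition.
    """
    low_obs = obs[obs["temperature_C"] <= T_split]
    high_obs = obs[obs["temperature_C"] > T_split]
    if low_obs.empty or high_obs.empty:
        raise NonIdentifiableError("T_split leaves an empty temperature partition")
    high = fit_att_one_phase(high_obs)

    if fix_k is not None and fix_k == 0.0:
        low = fit_att_one_phase(low_obs)
        ext = LowRangeExtension(k=0.0, T_i=T_split, p_maxi50=low.params.p_max50)
        low.params = ATTParams(p_max50=low.params.p_max50,
                               sigma_pmax=low.params.sigma_pmax,
                               theta_AT=low.params.theta_AT, T_b=low.params.T_b,
                               low_range_extension=ext)
        return low, high

    y = _probit_response(low_obs)
    T = low_obs["temperature_C"].to_numpy(dtype=float)
    p = low_obs["storage_days"].to_numpy(dtype=float)
    t = low_obs["time_h"].to_numpy(dtype=float)
    if np.unique(T).size < 2:
        raise NonIdentifiableError("low partition needs >= 2 distinct temperatures")
    if np.unique(p).size < 2:
        raise NonIdentifiableError("low partition needs >= 2 distinct storage times")
    T_max = float(T.min())

    def design(Tb):
        return np.column_stack([np.ones_like(p), T, p, 1.0 / ((T - Tb) * t)])

    def sse(Tb):
        try:
            _, rss = _ols(design(Tb), y)
        except NonIdentifiableError:
            return float("inf")
        return rss

    Tb = _profile_Tb(sse, T_max)
    coef, _ = _ols(design(Tb), y)
    c0, c1, c2, c3 = coef
    if c2 >= 0:
        raise NonIdentifiableError("germination does not decline with storage time")
    sigma = -1.0 / c2
    k = c1 * sigma
    theta_AT = -c3 * sigma
    flags = []
    p_maxi50 = high.params.p_max50
    # T_i / p_maxi50 split: anchored to the high-range median lifetime,
    # then T_i confined to the gap between the partitions.
    Ti_lo, Ti_hi = float(T.max()), float(high_obs["temperature_C"].min())
    if k > 1e-12:
        T_i = (p_maxi50 - c0 * sigma) / k
        if not Ti_lo <= T_i <= Ti_hi:
            T_i = min(max(T_i, Ti_lo), Ti_hi)
            p_maxi50 = c0 * sigma + k * T_i
            flags.append("T_i clamped to partition gap")
    else:
        k = max(k, 0.0)
        T_i = Ti_hi
        p_maxi50 = c0 * sigma
        flags.append("no low-range lifetime decline detected (k ~ 0)")
    ext = LowRangeExtension(k=k, T_i=T_i, p_maxi50=p_maxi50)
    params = ATTParams(p_max50=p_maxi50, sigma_pmax=sigma, theta_AT=theta_AT,
                       T_b=Tb, low_range_extension=ext)
    low = _make_result(params, y, design(Tb) @ coef, 6, low_obs, flags=flags)
    return low, high


# ---------------------------------------------------------------------------
# rate-line regressions and auxiliary fits


@dataclass
class GRLinesFit:
    """Per-percentile germination-rate lines with one shared constraint.

    ``mode="common_base"``: lines 1/t_g = slope_g·(T − T_b) converge on a
    shared base temperature; ``shared`` is T_b (°C) and ``intercepts``
    holds the per-percentile x-intercepts (all equal to T_b).
    ``mode="common_slope"``: lines 1/t_g = (T − T_m(g))/θ_Tm share the
    slope 1/θ_Tm; ``shared`` is the slope (1/(°C·h)) and ``intercepts``
    maps percent → T_m(g).
    """

    mode: str
    shared: float
    slopes: dict
    intercepts: dict
    r2: float


def fit_gr_lines(rates: pd.DataFrame, mode: str = "common_base") -> GRLinesFit:
    """Constrained linear fits of germination rate versus temperature.

    ``rates`` is the long table from :func:`percentile_times_table`
    (columns percent, temperature_C, time_h); rates are 1/time_h.
    """
    if mode not in ("common_base", "common_slope"):
        raise ValueError("mode must be 'common_base' or 'common_slope'")
    df = rates.dropna(subset=["time_h"]).copy()
    if df.empty:
        raise NonIdentifiableError("no finite percentile times to regress")
    df["rate"] = 1.0 / df["time_h"].to_numpy(dtype=float)
    percents = sorted(df["percent"].unique())
    T_all = df["temperature_C"].to_numpy(dtype=float)
    r = df["rate"].to_numpy(dtype=float)
    if np.unique(T_all).size < 2:
        raise NonIdentifiableError("need >= 2 temperatures for rate lines")
    tss = float(np.sum((r - r.mean()) ** 2))

    if mode == "common_base":

        def sse(Tb):
            total = 0.0
            for g in percents:
                sel = df["percent"] == g
                x = T_all[sel] - Tb
                y = r[sel]
                denom = float(x @ x)
                if denom == 0:
                    return float("inf")
                s = float(x @ y) / denom
                total += float(np.sum((y - s * x) ** 2))
            return total

        Tb = _profile_Tb(sse, float(T_all.min()))
        slopes = {}
        rss = 0.0
        for g in percents:
            sel = df["percent"] == g
            x = T_all[sel] - Tb
            yv = r[sel]
            s = float(x @ yv) / float(x @ x)
            slopes[g] = s
            rss += float(np.sum((yv - s * x) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        return GRLinesFit(mode=mode, shared=Tb, slopes=slopes,
                          intercepts={g: Tb for g in percents}, r2=r2)

    # common_slope: ANCOVA with per-percentile intercepts
    dummies = np.column_stack([(df["percent"] == g).to_numpy(float) for g in percents])
    X = np.column_stack([T_all, dummies])
    coef, rss = _ols(X, r)
    slope = float(coef[0])
    if slope <= 0:
        raise NonIdentifiableError("rates do not increase with temperature")
    intercepts = {g: -float(a) / slope for g, a in zip(percents, coef[1:])}
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return GRLinesFit(mode=mode, shared=slope,
                      slopes={g: slope for g in percents},
                      intercepts=intercepts, r2=r2)


def regress_inv_thetaA(temperatures, theta_A, form: str = "one_line",
                       T_split: float = 12.5) -> dict:
    """Regress 1/θ_A on temperature: one line, two segments, or quadratic.

    A linear 1/θ_A–temperature relation is the signature of a constant
    aging thermal time: 1/θ_A = (T − T_b)/θ_AT, so each linear segment
    reports the implied θ_AT = 1/slope and T_b = −intercept/slope.  The
    two-segment form splits at ``T_split`` and reports the pooled R²
    (1 − ΣSSE/total SS about the grand mean).
    """
    T = np.asarray(temperatures, dtype=float)
    y = 1.0 / np.asarray(theta_A, dtype=float)
    if T.shape != y.shape:
        raise ValueError("temperatures and theta_A must have equal length")
    tss = float(np.sum((y - y.mean()) ** 2))

    def line(Ts, ys):
        if Ts.size < 2 or np.unique(Ts).size < 2:
            raise NonIdentifiableError("need >= 2 distinct temperatures per segment")
        X = np.column_stack([Ts, np.ones_like(Ts)])
        coef, rss = _ols(X, ys)
        slope, intercept = float(coef[0]), float(coef[1])
        seg = {"slope": slope, "intercept": intercept, "sse": rss}
        if slope > 0:
            seg["theta_AT"] = 1.0 / slope
            seg["T_b"] = -intercept / slope
        return seg

    if form == "one_line":
        if T.size < 3:
            raise NonIdentifiableError("one_line needs >= 3 points")
        seg = line(T, y)
        r2 = 1.0 - seg["sse"] / tss if tss > 0 else 1.0
        return {"form": form, "r2": r2, "segments": [seg]}
    if form == "two_lines":
        lo = T <= T_split
        segs = [line(T[lo], y[lo]), line(T[~lo], y[~lo])]
        rss = segs[0]["sse"] + segs[1]["sse"]
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        return {"form": form, "r2": r2, "T_split": T_split, "segments": segs}
    if form == "quadratic":
        if T.size < 4:
            raise NonIdentifiableError("quadratic needs >= 4 points")
        coeffs = np.polyfit(T, y, 2)
        rss = float(np.sum((y - np.polyval(coeffs, T)) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        return {"form": form, "r2": r2, "coefficients": coeffs.tolist()}
    raise ValueError("form must be 'one_line', 'two_lines' or 'quadratic'")


def fit_viability_normal(storage_days, viability) -> ViabilityCurveParams:
    """Fit the viability-loss curve viability = Φ((μ − p)/σ) by least squares.

    The fit is on the viability (response) scale via nonlinear least
    squares, initialized from a probit-linear regression of the interior
    points.  Viability that does not decline with storage leaves σ with
    no admissible (positive) value and raises ``NonIdentifiableError``.
    """
    x = np.asarray(storage_days, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.size < 3:
        raise NonIdentifiableError("need >= 3 storage times")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("viability must lie in [0, 1]")
    interior = (y > 0) & (y < 1)
    if interior.sum() >= 2 and np.unique(x[interior]).size >= 2:
        z = norm.ppf(y[interior])
        X = np.column_stack([x[interior], np.ones(interior.sum())])
        coef, _ = _ols(X, z)
        slope, intercept = float(coef[0]), float(coef[1])
        if slope >= 0:
            raise NonIdentifiableError(
                "viability does not decline with storage (sigma would be negative)"
            )
        mu0, sigma0 = -intercept / slope, -1.0 / slope
    else:
        if np.unique(y).size < 2:
            raise NonIdentifiableError("constant viability: sigma unidentifiable")
        mu0, sigma0 = float(np.median(x)), max(float(x.max() - x.min()), 1.0) / 2

    def model(xx, mu, sigma):
        return norm.cdf((mu - xx) / sigma)

    popt, _ = curve_fit(model, x, y, p0=[mu0, sigma0],
                        bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=10000)
    return ViabilityCurveParams(mu=float(popt[0]), sigma=float(popt[1]))
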