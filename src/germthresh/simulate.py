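"""Synthetic seed-lot germination experiments.

The generator embodies the population assumption shared by all the
threshold models: each seed occupies one percentile ``u`` of the lot,
drawn Uniform(0,1), and *all* of its thresholds are the u-quantiles of
their distributions.  A single ranking therefore links a seed's thermal
time, minimum temperature and maximum lifetime — early-germinating seeds
are also the long-lived ones — which is exactly the coupling the
normalization transforms rely on.

The default :class:`SimulationDesign` reproduces the source experiment's
factorial layout: 6 temperatures (5–30 °C in 5 °C steps) × 8 storage
durations (0, 5, 10, 15, 20, 25, 45, 65 d) × 3 replicates of 50 seeds,
scored hourly up to 480 h (20 d, after which scoring stopped).

Observation noise is purely binomial, via individual-seed simulation; no
extra overdispersion is added.  Germination times are right-censored at
``max_duration`` and discretized to the recording interval.  A seed whose
effective aging meets or exceeds its lifetime quantile is dead and never
germinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import predict_fraction
from .params import ATTParams, MLTParams, MTTLowParams, MTTParams, TTParams

__all__ = ["SimulationDesign", "simulate_lot", "noiseless_grid", "seed_times"]

OBS_COLUMNS = ["temperature_C", "storage_days", "time_h", "replicate",
               "n_sown", "n_germ_cum"]


@dataclass(frozen=True)
class SimulationDesign:
    """Factorial layout and scoring scheme of a germination experiment."""

    temperatures: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    storage_days: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 45.0, 65.0)
    n_seeds: int = 50
    n_replicates: int = 3
    recording_interval: float = 1.0
    max_duration: float = 480.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds <= 0 or self.n_replicates <= 0:
            raise ValueError("seed and replicate counts must be positive")
        if self.recording_interval <= 0 or self.max_duration <= 0:
            raise ValueError("recording interval and duration must be positive")

    @property
    def observation_times(self) -> np.ndarray:
        return np.arange(self.recording_interval,
                         self.max_duration + self.recording_interval / 2,
                         self.recording_interval)


def seed_times(params, u, T: float, p: float) -> np.ndarray:
    """Germination times (h) of seeds at percentiles ``u`` for one treatment.

    ``inf`` marks a seed that never germinates there: temperature at or
    below its threshold, or dead from aging.
    """
    z = norm.ppf(np.asarray(u, dtype=float))
    if isinstance(params, TTParams):
        if T <= params.T_b:
            return np.full(z.shape, np.inf)
        theta = np.exp(np.log(params.theta_T50) + params.sigma_lnTheta * z)
        return theta / (T - params.T_b)
    if isinstance(params, MTTLowParams):
        Tm = params.T_m50 + params.sigma_Tm * z
        with np.errstate(divide="ignore"):
            t = np.where(T > Tm, params.theta_Tm / np.clip(T - Tm, 1e-300, None), np.inf)
        return t
    if isinstance(params, MTTParams):
        branch = params.low if T <= params.T_split else params.high
        return seed_times(branch, u, T, p)
    if isinstance(params, MLTParams):
        pmax = params.p_max50 - params.sigma_pmax * z
        remaining = pmax - p
        with np.errstate(divide="ignore"):
            return np.where(remaining > 0,
                            params.theta_A / np.clip(remaining, 1e-300, None), np.inf)
    if isinstance(params, ATTParams):
        if T <= params.T_b:
            return np.full(z.shape, np.inf)
        ext = params.low_range_extension
        if ext is not None and T < ext.T_i:
            median = ext.p_maxi50 - ext.k * (ext.T_i - T)
        else:
            median = params.p_max50
        pmax = median - params.sigma_pmax * z
        remaining = pmax - p
        with np.errstate(divide="ignore"):
            return np.where(
                remaining > 0,
                params.theta_AT / ((T - params.T_b) * np.clip(remaining, 1e-300, None)),
                np.inf,
            )
    raise TypeError(f"unsupported parameter record: {type(params).__name__}")


def simulate_lot(params, design: SimulationDesign) -> pd.DataFrame:
    """Simulate a full factorial germination experiment.

    Returns the tidy observation table (one row per treatment × replicate
    × recording time, cumulative counts).  Bit-reproducible for a fixed
    ``design.rng_seed``.
    """
    rng = np.random.default_rng(design.rng_seed)
    times = design.observation_times
    frames = []
    for T in design.temperatures:
        for p in design.storage_days:
            for rep in range(1, design.n_replicates + 1):
                u = rng.uniform(size=design.n_seeds)
                tg = seed_times(params, u, float(T), float(p))
                counts = (tg[:, None] <= times[None, :]).sum(axis=0)
                frames.append(pd.DataFrame({
                    "temperature_C": T,
                    "storage_days": p,
                    "time_h": times,
                    "replicate": f"R{rep}",
                    "n_sown": design.n_seeds,
                    "n_germ_cum": counts,
                }))
    return pd.concat(frames, ignore_index=True)[OBS_COLUMNS]


def noiseless_grid(params, design: SimulationDesign) -> pd.DataFrame:
    """Exact expected cumulative fractions on the design grid (no sampling).

    Same table layout as :func:`simulate_lot` with a single "expected"
    replicate and real-valued counts ``n_sown × predicted fraction``.
    """
    times = design.observation_times
    frames = []
    for T in design.temperatures:
        for p in design.storage_days:
            if isinstance(params, ATTParams) and T <= params.T_b:
                frac = np.zeros_like(times)
            else:
                frac = np.asarray(predict_fraction(params, T=float(T),
                                                   p=float(p), t=times))
            frames.append(pd.DataFrame({
                "temperature_C": T,
                "storage_days": p,
                "time_h": times,
                "replicate": "expected",
                "n_sown": float(design.n_seeds),
                "n_germ_cum": design.n_seeds * frac,
            }))
    return pd.concat(frames, ignore_index=True)[OBS_COLUMNS]
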