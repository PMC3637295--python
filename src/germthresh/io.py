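"""Reading, writing and reproducible workflow runs.

One flat tidy input format is accepted: a delimited text table with header
``temperature_C, storage_days, time_h, replicate, n_sown, n_germ_cum``.
Counts, never pre-computed fractions, keep the binomial structure of the
data available to the fitting routines.  Validation is strict — a
decreasing cumulative count is an error naming the offending series and
time, not something to repair silently.

The workflow functions (:func:`simulate_run`, :func:`fit_run`,
:func:`predict_run`, :func:`normalize_run`, :func:`compare_run`) are the
package's operational surface: each takes in-memory inputs, optionally
writes its result table with a provenance header (the exact configuration
echoed as JSON comment lines), and returns the result.  Two runs with the
same configuration and seed produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import fitting, models, simulate
from .fitting import FitResult
from .params import (
    ATTParams,
    MLTParams,
    MTTParams,
    TTParams,
    params_to_dict,
)

__all__ = [
    "DataValidationError",
    "REQUIRED_COLUMNS",
    "read_observations",
    "write_observations",
    "write_fit_report",
    "fit_report_frame",
    "simulate_run",
    "fit_run",
    "predict_run",
    "normalize_run",
    "compare_run",
]

REQUIRED_COLUMNS = ["temperature_C", "storage_days", "time_h", "replicate",
                    "n_sown", "n_germ_cum"]
_NUMERIC = ["temperature_C", "storage_days", "time_h", "n_sown", "n_germ_cum"]


class DataValidationError(ValueError):
    """Malformed observation table."""


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing required columns: {missing}")
    df = df.copy()
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad = df.index[df["n_germ_cum"] > df["n_sown"]]
    if len(bad):
        raise DataValidationError(
            f"n_germ_cum exceeds n_sown at rows {list(bad[:5])}"
        )
    bad = df.index[(df["time_h"] <= 0) | (df["n_sown"] <= 0) | (df["n_germ_cum"] < 0)]
    if len(bad):
        raise DataValidationError(
            f"non-positive time/counts at rows {list(bad[:5])}"
        )
    for key, grp in df.groupby(fitting.SERIES_COLS, sort=False):
        grp = grp.sort_values("time_h")
        drops = np.diff(grp["n_germ_cum"].to_numpy()) < 0
        if drops.any():
            t_bad = grp["time_h"].to_numpy()[1:][drops][0]
            raise DataValidationError(
                "cumulative germination decreases in series "
                f"(temperature={key[0]}, storage={key[1]}, replicate={key[2]}) "
                f"at time_h={t_bad}"
            )
    return df


def read_observations(path) -> pd.DataFrame:
    """Read and validate a tidy germination observation table (CSV/TSV).

    Lines starting with ``#`` (provenance headers) are ignored.  The
    delimiter is sniffed from the header line (comma or tab).
    """
    path = Path(path)
    sep = ","
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                if "\t" in line and "," not in line:
                    sep = "\t"
                break
    df = pd.read_csv(path, comment="#", sep=sep)
    return _validate(df)


def _provenance_header(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str)
    return f"# germthresh run\n# config: {payload}\n"


def write_observations(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    """Write an observation table as CSV, with an optional provenance header."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_provenance_header(config))
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# fit reporting


def fit_report_frame(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Goodness-of-fit table, one row per named fit."""
    rows = []
    for name, fr in fits.items():
        rows.append({
            "fit": name,
            "model": type(fr.params).__name__,
            "n_obs": fr.n_obs,
            "k_params": fr.k_params,
            "r2": fr.r2,
            "adjusted_r2": fr.adjusted_r2,
            "rmse": fr.rmse,
            "aic": fr.aic,
            "converged": fr.converged,
            "flags": ";".join(fr.flags),
        })
    return pd.DataFrame(rows)


def write_fit_report(fits: dict[str, FitResult], report_path,
                     params_path=None, config: Optional[dict] = None) -> None:
    """Write the goodness table (CSV) and, optionally, parameters (JSON)."""
    with open(report_path, "w") as fh:
        if config is not None:
            fh.write(_provenance_header(config))
        fit_report_frame(fits).to_csv(fh, index=False)
    if params_path is not None:
        payload = {name: params_to_dict(fr.params) for name, fr in fits.items()}
        if config is not None:
            payload["_config"] = config
        Path(params_path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# workflows


def simulate_run(params, design: simulate.SimulationDesign,
                 out_path=None) -> pd.DataFrame:
    """Simulate a seed lot; optionally write it with full provenance."""
    df = simulate.simulate_lot(params, design)
    if out_path is not None:
        config = {"command": "simulate", "model": params_to_dict(params),
                  "design": dataclasses.asdict(design)}
        write_observations(df, out_path, config=config)
    return df


def fit_run(obs: pd.DataFrame, model: str, T_split: float = 12.5,
            censor: bool = True, out_report=None, out_params=None
            ) -> dict[str, FitResult]:
    """Fit one model family to an observation table.

    ``model`` is one of ``tt``, ``mtt``, ``mlt``, ``att1``, ``att2``.
    MLT fits are per temperature (one result per temperature present).
    Returns ``{fit name: FitResult}``.
    """
    data = fitting.regression_points(obs, censor=censor)
    if model == "tt":
        fits = {"tt": fitting.fit_tt(data)}
    elif model == "mtt":
        low, high = fitting.fit_mtt(data, T_split=T_split)
        fits = {"mtt_low": low, "mtt_high": high}
    elif model == "mlt":
        fits = {}
        for T, grp in data.groupby("temperature_C", sort=True):
            fits[f"mlt_{T:g}C"] = fitting.fit_mlt(grp)
    elif model == "att1":
        fits = {"att_one_phase": fitting.fit_att_one_phase(data)}
    elif model == "att2":
        low, high = fitting.fit_att_two_phase(data, T_split=T_split)
        fits = {"att_low": low, "att_high": high}
    else:
        raise ValueError(f"unknown model {model!r}; expected tt/mtt/mlt/att1/att2")
    if out_report is not None or out_params is not None:
        config = {"command": "fit", "model": model, "T_split": T_split,
                  "censor": censor}
        write_fit_report(fits, out_report, params_path=out_params, config=config)
    return fits


def predict_run(params, temperatures: Sequence[float],
                storage_days: Sequence[float], times: Sequence[float],
                out_path=None) -> pd.DataFrame:
    """Predicted cumulative fractions on a (T, p, t) grid."""
    rows = []
    for T in temperatures:
        for p in storage_days:
            frac = models.predict_fraction(params, T=float(T), p=float(p),
                                           t=np.asarray(times, dtype=float))
            rows.append(pd.DataFrame({
                "temperature_C": T, "storage_days": p, "time_h": times,
                "predicted_fraction": np.asarray(frac),
            }))
    df = pd.concat(rows, ignore_index=True)
    if out_path is not None:
        config = {"command": "predict", "model": params_to_dict(params),
                  "temperatures": list(temperatures),
                  "storage_days": list(storage_days)}
        with open(out_path, "w") as fh:
            fh.write(_provenance_header(config))
            df.to_csv(fh, index=False)
    return df


def normalize_run(obs: pd.DataFrame, params, out_path=None) -> pd.DataFrame:
    """Normalize observed germination times with fitted model parameters.

    With :class:`MLTParams`, adds ``normalized_time_h`` — observed times
    mapped onto the control (zero-storage) course.  With
    :class:`ATTParams`, adds ``theta_NT_Ch`` — the normalized thermal
    time collapsing temperature and storage.  Rows whose fraction is 0, 1
    or a dead percentile are dropped.
    """
    if not isinstance(params, (MLTParams, ATTParams)):
        raise TypeError("normalization needs MLT or ATT parameters")
    col = "normalized_time_h" if isinstance(params, MLTParams) else "theta_NT_Ch"
    rows = []
    for _, row in obs.iterrows():
        frac = row["n_germ_cum"] / row["n_sown"]
        if not 0.0 < frac < 1.0:
            continue
        try:
            if isinstance(params, MLTParams):
                pmax_g = models.pmax_quantile(params, frac)
                value = models.normalize_storage_time(
                    row["time_h"], row["storage_days"], pmax_g)
            else:
                value = models.normalized_thermal_time(
                    params, row["temperature_C"], row["storage_days"],
                    row["time_h"], frac)
        except ValueError:
            continue
        rec = row.to_dict()
        rec["fraction"] = frac
        rec[col] = value
        rows.append(rec)
    df = pd.DataFrame(rows, columns=list(obs.columns) + ["fraction", col])
    if out_path is not None:
        config = {"command": "normalize", "model": params_to_dict(params)}
        with open(out_path, "w") as fh:
            fh.write(_provenance_header(config))
            df.to_csv(fh, index=False)
    return df


def compare_run(obs: pd.DataFrame, pair: str = "tt_vs_mtt",
                T_split: float = 12.5, out_path=None) -> pd.DataFrame:
    """Fit two rival models on the same censored data and rank them by AIC.

    ``pair`` is ``tt_vs_mtt`` (one- vs two-phased thermal response of
    control seeds) or ``att1_vs_att2`` (one- vs two-phased aging thermal
    time).  Reports total AIC, RMSE and adjusted R² per model plus the
    deltas; the lower AIC marks the likelier model.
    """
    data = fitting.regression_points(obs)
    if pair == "tt_vs_mtt":
        single = [fitting.fit_tt(data)]
        split = list(fitting.fit_mtt(data, T_split=T_split))
        names = ["tt", "mtt"]
    elif pair == "att1_vs_att2":
        single = [fitting.fit_att_one_phase(data)]
        split = list(fitting.fit_att_two_phase(data, T_split=T_split))
        names = ["att_one_phase", "att_two_phase"]
    else:
        raise ValueError("pair must be 'tt_vs_mtt' or 'att1_vs_att2'")

    def summarize(name, fits):
        n = sum(f.n_obs for f in fits)
        rss = sum(float(f.residuals @ f.residuals) for f in fits)
        return {
            "model": name,
            "n_obs": n,
            "k_params": sum(f.k_params for f in fits),
            "aic": fitting.combined_aic(fits),
            "rmse": float(np.sqrt(rss / n)),
            "adjusted_r2": float(np.mean([f.adjusted_r2 for f in fits])),
        }

    df = pd.DataFrame([summarize(names[0], single), summarize(names[1], split)])
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["preferred"] = df["aic"] == df["aic"].min()
    if out_path is not None:
        config = {"command": "compare", "pair": pair, "T_split": T_split}
        with open(out_path, "w") as fh:
            fh.write(_provenance_header(config))
            df.to_csv(fh, index=False)
    return df
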