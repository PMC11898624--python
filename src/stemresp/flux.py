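"""Flux computation, apparent respiratory quotient, outlier screening and
time aggregation.

The closed-chamber concentration slope (ppm s⁻¹) converts to an areal flux
via the gas law:

    Flux = |ΔC/Δt| · (V/A) · P / (R·T)      [µmol m⁻² s⁻¹]

with chamber volume V (m³), enclosed stem area A (m²), pressure P (kPa),
R = 0.008314 m³ kPa K⁻¹ mol⁻¹ and T in kelvin.  The apparent respiratory
quotient is the ratio of the CO₂ slope to the negative dilution-corrected
O₂ slope; the geometric and thermodynamic factors cancel, so ARQ needs no
chamber calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import (QCResult, dilution_correct_o2, extract_fit_window,
                      fit_slope, qc_flags, rh_to_h2o)
from .constants import CONSTANTS, PhysConstants, celsius_to_kelvin

__all__ = [
    "FluxRecord",
    "compute_flux",
    "compute_arq",
    "iqr_filter",
    "iqr_bounds",
    "aggregate_fluxes",
    "process_cycle",
    "process_cycles",
]


@dataclass(frozen=True)
class FluxRecord:
    """Per-cycle pipeline output.

    ``i_o2`` is stored as a positive magnitude; ``arq`` is NaN when the
    corrected O₂ slope is non-negative (ratio undefined).
    """

    time: pd.Timestamp
    tree_id: str
    treatment: str
    cycle_id: str
    e_co2: float
    i_o2: float
    arq: float
    slope_co2: float
    slope_o2_corr: float
    r2_co2: float
    r2_o2: float
    rh_mean: float
    qc: QCResult
    interpolated: bool = False


def compute_flux(slope_ppm_s: float, chamber, env,
                 constants: PhysConstants = CONSTANTS) -> float:
    """Convert a concentration slope to an areal flux (µmol m⁻² s⁻¹).

    The slope is taken as an absolute value; direction (efflux vs influx)
    is carried by which gas it belongs to.
    """
    T_K = celsius_to_kelvin(env.temp_C)
    volume_m3 = chamber.volume_cm3 * 1e-6
    if volume_m3 <= 0 or chamber.area_m2 <= 0 or env.pressure_kPa <= 0 \
            or T_K <= 0:
        raise ValueError("V, A, P and T must all be positive")
    return (abs(slope_ppm_s) * (volume_m3 / chamber.area_m2)
            * env.pressure_kPa / (constants.R_gas * T_K))


def compute_arq(slope_co2: float, slope_o2_corr: float) -> float:
    """ARQ = slope_CO₂ / (−slope_O₂corr); NaN when the O₂ slope is ≥ 0."""
    if slope_o2_corr >= 0:
        return float("nan")
    return slope_co2 / (-slope_o2_corr)


def iqr_bounds(values) -> tuple[float, float]:
    """Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR (type-7 quantiles)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def iqr_filter(values):
    """Retain values inside the Tukey fences.

    Quartiles use linear interpolation (the common type-7 convention).
    Fewer than 4 finite values cannot support quartile estimation; the
    input is passed through unchanged with ``warned=True``.

    Returns
    -------
    (retained, mask, warned) : retained values as an ndarray, a boolean
    keep-mask aligned with the input (NaNs are dropped), and the
    small-sample flag.
    """
    v = np.asarray(values, dtype=float)
    finite = ~np.isnan(v)
    if finite.sum() < 4:
        return v[finite], finite, True
    lo, hi = iqr_bounds(v)
    mask = finite & (v >= lo) & (v <= hi)
    return v[mask], mask, False


def process_cycle(cycle, env=None, r2_threshold: float = 0.96,
                  rh_threshold_pct: float = 99.0,
                  constants: PhysConstants = CONSTANTS) -> FluxRecord:
    """Full single-cycle chain: window → H₂O → dilution → slopes → QC → flux.

    ``env`` defaults to the cycle's own recorded temperature, pressure and
    humidity (fit-window means), which is how field logs are processed.
    """
    win = extract_fit_window(cycle)
    h2o_ppm = rh_to_h2o(win.rh_pct, win.temp_C, win.pressure_kPa)
    o2_corr = dilution_correct_o2(win.o2_ppm_wet, h2o_ppm, win.co2_ppm)
    # CO2 is a trace gas, but referencing it to the same inert matrix
    # removes the residual (second-order) dilution bias at no cost
    matrix = 1e6 - win.o2_ppm_wet - win.co2_ppm - h2o_ppm
    co2_corr = win.co2_ppm * (matrix[0] / matrix)
    fit_co2 = fit_slope(win.t_s, co2_corr)
    fit_o2 = fit_slope(win.t_s, o2_corr)
    rh_mean = float(np.mean(win.rh_pct))
    qc = qc_flags(fit_co2, fit_o2, rh_mean, r2_threshold, rh_threshold_pct)

    if env is None:
        from .synthetic import EnvState
        env = EnvState(temp_C=float(np.mean(win.temp_C)),
                       pressure_kPa=float(np.mean(win.pressure_kPa)),
                       rh_pct=min(rh_mean, 100.0))
    e_co2 = compute_flux(fit_co2.slope_ppm_s, cycle.chamber, env, constants)
    i_o2 = compute_flux(fit_o2.slope_ppm_s, cycle.chamber, env, constants)
    return FluxRecord(
        time=cycle.start_time, tree_id=cycle.chamber.tree_id,
        treatment=cycle.chamber.treatment, cycle_id=cycle.cycle_id,
        e_co2=e_co2, i_o2=i_o2,
        arq=compute_arq(fit_co2.slope_ppm_s, fit_o2.slope_ppm_s),
        slope_co2=fit_co2.slope_ppm_s, slope_o2_corr=fit_o2.slope_ppm_s,
        r2_co2=fit_co2.r2, r2_o2=fit_o2.r2, rh_mean=rh_mean, qc=qc)


def process_cycles(cycles, iqr_group: str | None = "tree_id",
                   r2_threshold: float = 0.96,
                   rh_threshold_pct: float = 99.0,
                   constants: PhysConstants = CONSTANTS) -> pd.DataFrame:
    """Process many cycles into a QC'd flux table.

    Cycles failing QC keep their row with ``qc_overall=False`` and NaN
    fluxes.  The ARQ outlier screen (Tukey fences) is applied within each
    ``iqr_group`` (default per tree; ``None`` pools everything) and marks
    ``arq_outlier`` rather than deleting rows.
    """
    rows = []
    for cyc in cycles:
        try:
            rec = process_cycle(cyc, None, r2_threshold, rh_threshold_pct,
                                constants)
        except ValueError:
            continue  # cycle too short for the fit window
        rows.append({
            "time": rec.time, "tree_id": rec.tree_id,
            "treatment": rec.treatment, "cycle_id": rec.cycle_id,
            "e_co2": rec.e_co2 if rec.qc.overall else np.nan,
            "i_o2": rec.i_o2 if rec.qc.overall else np.nan,
            "arq": rec.arq if rec.qc.overall else np.nan,
            "slope_co2": rec.slope_co2, "slope_o2_corr": rec.slope_o2_corr,
            "r2_co2": rec.r2_co2, "r2_o2": rec.r2_o2,
            "rh_mean": rec.rh_mean, "qc_overall": rec.qc.overall,
            "interpolated": False,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["arq_outlier"] = False
    groups = [(None, df)] if iqr_group is None else df.groupby(iqr_group)
    for _, g in groups:
        _, mask, warned = iqr_filter(g["arq"].to_numpy())
        if not warned:
            keep_idx = g.index[mask]
            drop = g.index.difference(keep_idx)
            drop = drop[~df.loc[drop, "arq"].isna()]
            df.loc[drop, "arq_outlier"] = True
    df.loc[df["arq_outlier"], "arq"] = np.nan
    return df


def aggregate_fluxes(df: pd.DataFrame,
                     value_cols=("e_co2", "i_o2", "arq")
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """6-hour and daily averaging of a flux table.

    6-h bins are aligned at 00/06/12/18 local; a daily mean is emitted
    only when all four 6-h bins of that calendar day are populated (the
    complete-24-h rule), separately per value column.  Grouping is per
    tree; treatment labels are carried along.
    """
    if df.empty:
        raise ValueError("flux table is empty")
    d = df.copy()
    d["bin6"] = d["time"].dt.floor("6h")
    d["date"] = d["time"].dt.floor("D")

    six = (d.groupby(["tree_id", "treatment", "bin6"])[list(value_cols)]
           .mean().reset_index())
    six["date"] = six["bin6"].dt.floor("D")

    daily_rows = []
    for (tree, treat, date), g in six.groupby(["tree_id", "treatment", "date"]):
        row = {"tree_id": tree, "treatment": treat, "date": date}
        for col in value_cols:
            bins = g.loc[g[col].notna(), "bin6"].dt.hour.unique()
            row[col] = g[col].mean() if len(bins) == 4 else np.nan
        daily_rows.append(row)
    daily = pd.DataFrame(daily_rows)
    return six.drop(columns="date"), daily
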