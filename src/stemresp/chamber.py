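"""Raw closed-chamber cycle processing: humidity conversion, O₂ dilution
correction, fit-window extraction, slope regression, QC flags and gap filling.

A measurement cycle is 45 min of closed-chamber accumulation sampled every
10 s, followed by a 15-min flush.  Fluxes are derived from the linear change
of CO₂ (increase) and dilution-corrected O₂ (decrease) over the 5–25 min
window of the closed phase; cycles failing the regression-quality or
humidity screens are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SlopeFit",
    "QCResult",
    "magnus_saturation_vp_hpa",
    "rh_to_h2o",
    "dilution_correct_o2",
    "extract_fit_window",
    "fit_slope",
    "qc_flags",
    "fill_gaps",
]

# Fit window on the closed phase: drop the first 5 min (pressure transients
# after flushing), keep the following 20 min.  Half-open on the 10-s grid.
FIT_WINDOW_START_S = 300.0
FIT_WINDOW_END_S = 1500.0

# QC defaults: minimum R² per-gas, maximum mean relative humidity.
R2_THRESHOLD = 0.96
RH_THRESHOLD_PCT = 99.0


@dataclass(frozen=True)
class SlopeFit:
    """Ordinary-least-squares fit of concentration (ppm) on time (s)."""

    slope_ppm_s: float
    intercept_ppm: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("slope fit requires at least 3 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of range: {self.r2}")


@dataclass(frozen=True)
class QCResult:
    """Per-cycle quality flags; ``overall`` is the conjunction of the rest."""

    pass_r2_co2: bool
    pass_r2_o2: bool
    pass_rh: bool
    pass_sign: bool

    @property
    def overall(self) -> bool:
        return (self.pass_r2_co2 and self.pass_r2_o2
                and self.pass_rh and self.pass_sign)


def magnus_saturation_vp_hpa(temp_C):
    """Saturation water-vapor pressure (hPa) by the Magnus formula.

    Uses the WMO-recommended constants: e_sat = 6.112·exp(17.62·T/(243.12+T)).
    """
    temp_C = np.asarray(temp_C, dtype=float)
    return 6.112 * np.exp(17.62 * temp_C / (243.12 + temp_C))


def rh_to_h2o(rh_pct, temp_C, pressure_kPa):
    """Convert relative humidity to water-vapor mole fraction in ppm.

    χ_H2O = (RH/100) · e_sat(T) / P, expressed in ppm.  Scalar or
    elementwise on arrays.
    """
    rh_pct = np.asarray(rh_pct, dtype=float)
    pressure_kPa = np.asarray(pressure_kPa, dtype=float)
    if np.any(rh_pct < 0) or np.any(rh_pct > 100):
        raise ValueError("relative humidity must be within 0–100%")
    if np.any(pressure_kPa <= 0):
        raise ValueError("pressure must be positive")
    e_sat_kpa = magnus_saturation_vp_hpa(temp_C) / 10.0  # hPa → kPa
    if np.any(pressure_kPa <= e_sat_kpa * (rh_pct / 100.0)):
        raise ValueError("vapor pressure exceeds total pressure")
    frac = (rh_pct / 100.0) * e_sat_kpa / pressure_kPa
    out = frac * 1e6
    return float(out) if out.ndim == 0 else out


def dilution_correct_o2(o2_ppm_wet, h2o_ppm, co2_ppm,
                        ref_matrix_ppm: float | None = None):
    """Remove the dilution signal from a measured (wet) O₂ series.

    O₂ is a non-trace gas: changes in water vapor and CO₂ — and in O₂
    itself — alter the total molar content of the headspace and hence the
    O₂ mole fraction even without any O₂ exchange.  The only headspace
    component the chamber neither adds nor removes is the inert N₂ + Ar
    matrix, so the ratio of O₂ to that matrix changes one-for-one with O₂
    exchange.  The corrected series is that ratio rescaled to ppm of the
    initial headspace:

        o2_corr(t) = o2(t) · M_ref / M(t),
        M(t) = 10⁶ − co2(t) − h2o(t) − o2(t)   [inert-matrix ppm]

    with ``M_ref`` defaulting to ``M`` at the first sample.  The time
    derivative of ``o2_corr`` then equals the molar O₂ exchange rate per
    initial headspace mole, the same basis on which the (trace) CO₂ slope
    is read, so slope ratios and Eq.-style flux conversion are unbiased.
    """
    o2 = np.atleast_1d(np.asarray(o2_ppm_wet, dtype=float))
    h2o = np.broadcast_to(np.asarray(h2o_ppm, dtype=float), o2.shape)
    co2 = np.broadcast_to(np.asarray(co2_ppm, dtype=float), o2.shape)
    matrix = 1e6 - o2 - h2o - co2
    if np.any(matrix <= 0):
        raise ValueError("O2 + H2O + CO2 mole fractions must total below 1")
    ref = matrix[0] if ref_matrix_ppm is None else float(ref_matrix_ppm)
    out = o2 * (ref / matrix)
    return float(out[0]) if np.isscalar(o2_ppm_wet) and out.size == 1 else out


def extract_fit_window(cycle, start_s: float = FIT_WINDOW_START_S,
                       end_s: float = FIT_WINDOW_END_S):
    """Return the subset of a cycle inside the half-open window [start, end).

    The default window keeps minutes 5–25 of the closed phase: the first
    five minutes are discarded because chamber closure perturbs pressure,
    and restricting to the first 20 min thereafter keeps the accumulation
    in its linear range.
    """
    if cycle.t_s[-1] < end_s:
        raise ValueError(
            f"cycle ends at {cycle.t_s[-1]:.0f} s; "
            f"needs to span at least {end_s:.0f} s")
    mask = (cycle.t_s >= start_s) & (cycle.t_s < end_s)
    return cycle.subset(mask)


def fit_slope(t_s, conc_ppm) -> SlopeFit:
    """OLS regression of concentration on time; r² is squared Pearson r.

    A perfectly constant concentration series has undefined r²; by
    convention it is reported as slope 0 / r² 0 so downstream QC fails it.
    """
    t = np.asarray(t_s, dtype=float)
    c = np.asarray(conc_ppm, dtype=float)
    if t.size < 3 or c.size != t.size:
        raise ValueError("need at least 3 paired points")
    if np.ptp(t) == 0:
        raise ValueError("time vector is constant")
    if np.ptp(c) == 0:
        return SlopeFit(0.0, float(c[0]), 0.0, int(t.size))
    res = stats.linregress(t, c)
    return SlopeFit(float(res.slope), float(res.intercept),
                    float(res.rvalue) ** 2, int(t.size))


def qc_flags(fit_co2: SlopeFit, fit_o2: SlopeFit, rh_window_pct: float,
             r2_threshold: float = R2_THRESHOLD,
             rh_threshold_pct: float = RH_THRESHOLD_PCT) -> QCResult:
    """Screen a cycle on regression quality, humidity and slope signs.

    ``fit_o2`` must be the fit of the dilution-corrected O₂ series.  The R²
    screen is applied to each gas separately (the conservative reading);
    ``rh_window_pct`` is the mean relative humidity over the fit window.
    A physically sensible cycle has CO₂ rising and corrected O₂ falling.
    """
    return QCResult(
        pass_r2_co2=fit_co2.r2 >= r2_threshold,
        pass_r2_o2=fit_o2.r2 >= r2_threshold,
        pass_rh=rh_window_pct <= rh_threshold_pct,
        pass_sign=(fit_co2.slope_ppm_s > 0) and (fit_o2.slope_ppm_s < 0),
    )


def fill_gaps(series: pd.Series, max_gap_h: float = 2.0) -> pd.DataFrame:
    """Linearly interpolate gaps strictly shorter than ``max_gap_h``.

    ``series`` must carry a DatetimeIndex on a regular nominal grid with
    missing cycles present as NaN.  A gap's duration is the number of
    consecutive missing points times the grid step.  Returns a DataFrame
    with columns ``value`` and ``interpolated`` (True where filled); longer
    gaps stay missing.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must have a DatetimeIndex")
    if len(series) < 2:
        return pd.DataFrame({"value": series, "interpolated": False})
    steps = np.diff(series.index.values.astype("int64"))
    step_ns = np.min(steps)
    if step_ns <= 0 or np.any(steps % step_ns):
        raise ValueError("index is not on a regular nominal grid")
    step_h = step_ns / 3.6e12

    values = series.to_numpy(dtype=float)
    missing = np.isnan(values)
    filled = series.interpolate(method="time", limit_area="inside").to_numpy()

    keep = missing.copy()  # runs short enough to accept the interpolation
    i = 0
    n = len(values)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            run_h = (j - i) * step_h
            if run_h >= max_gap_h or i == 0 or j == n:
                keep[i:j] = False  # too long, or no flanking value
            i = j
        else:
            i += 1
    out = values.copy()
    out[keep] = filled[keep]
    return pd.DataFrame({"value": out, "interpolated": keep},
                        index=series.index)
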