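"""Forward simulation of everything the field campaign measured.

Every downstream estimator in this package (slope → flux → ARQ chain,
flask isotope chain, stained-section coverage estimator) is validated by
parameter recovery against this module: the simulator knows the true stem
CO₂ efflux, respiratory quotient, substrate mixture, carbon age and lipid
coverage, and produces the raw observables — 10-s chamber sensor logs,
flask samples and RGB section images — with configurable noise.

The chamber model is a well-mixed fixed-volume headspace at constant
temperature and pressure within one cycle.  Each 10-s step the enclosed
stem adds ``resp_flux·A·Δt`` µmol CO₂, removes ``resp_flux/rq_true·A·Δt``
µmol O₂ and evaporates ``evap_rate·A·Δt`` µmol H₂O (clamped at saturation
via the Magnus relation); reported sensor values are wet mole fractions
(component over total moles), so the measured O₂ embeds the dilution
effect that the processing chain must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chamber import magnus_saturation_vp_hpa
from .constants import (AMBIENT_CO2_PPM, AMBIENT_D13C, AMBIENT_O2_PPM,
                        CONSTANTS, celsius_to_kelvin)
from .isotopes import AtmosphereRecord, FlaskSample

__all__ = [
    "SimulationConfig",
    "ChamberSpec",
    "EnvState",
    "RawCycle",
    "SubstrateMix",
    "OROImage",
    "simulate_cycle",
    "simulate_campaign",
    "simulate_flask",
    "flask_observed_d13c",
    "make_linear_atmosphere",
    "simulate_oro_image",
    "cycles_to_csv",
    "cycles_from_csv",
    "flasks_to_csv",
]

D13C_CARB_DEFAULT = -27.11
D13C_LIPID_DEFAULT = -31.14


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated chamber campaign.

    ``resp_flux`` is the stem CO₂ efflux in µmol m⁻² s⁻¹, ``rq_true`` the
    respiratory quotient (CO₂ released per O₂ consumed), ``evap_rate`` the
    bark evaporation in µmol H₂O m⁻² s⁻¹.  Noise SDs apply to the CO₂ and
    wet-O₂ sensor readings; ``drift_ppm_per_day`` is a linear CO₂-sensor
    drift.  The cycle layout is 45 min closed + 15 min flush at a 10-s
    cadence.  ``diel_temp`` is (mean °C, amplitude °C) of the sinusoidal
    diel air-temperature course applied between cycles.
    """

    resp_flux: float = 2.0
    rq_true: float = 1.0
    evap_rate: float = 0.5
    noise_sd_co2: float = 0.0
    noise_sd_o2: float = 0.0
    drift_ppm_per_day: float = 0.0
    cycle_closed_s: int = 2700
    cycle_flush_s: int = 900
    sample_interval_s: int = 10
    seed: int = 0
    diel_temp: tuple[float, float] = (15.0, 5.0)

    def __post_init__(self) -> None:
        if self.resp_flux <= 0:
            raise ValueError("resp_flux must be positive")
        if not (0.4 <= self.rq_true <= 1.3):
            raise ValueError("rq_true must lie within 0.4–1.3")
        if min(self.noise_sd_co2, self.noise_sd_o2, self.evap_rate) < 0:
            raise ValueError("noise SDs and evap_rate must be non-negative")
        if (self.cycle_closed_s + self.cycle_flush_s) % self.sample_interval_s:
            raise ValueError("cycle length must be divisible by the cadence")


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and identity of one stem chamber."""

    volume_cm3: float = 100.0
    area_m2: float = 0.0028
    tree_id: str = "T1"
    treatment: str = "control"

    def __post_init__(self) -> None:
        if not (50.0 <= self.volume_cm3 <= 150.0):
            raise ValueError("chamber volume outside plausible 50–150 cm³")
        if self.area_m2 <= 0:
            raise ValueError("stem surface area must be positive")


@dataclass(frozen=True)
class EnvState:
    """Ambient conditions at cycle start."""

    temp_C: float = 20.0
    pressure_kPa: float = 101.325
    rh_pct: float = 70.0

    def __post_init__(self) -> None:
        if self.pressure_kPa <= 0:
            raise ValueError("pressure must be positive")
        if not (0.0 <= self.rh_pct <= 100.0):
            raise ValueError("RH must be within 0–100%")
        if not (-30.0 <= self.temp_C <= 50.0):
            raise ValueError("temperature outside −30…50 °C")


@dataclass
class RawCycle:
    """One closed-chamber measurement cycle at 10-s cadence.

    ``o2_ppm_wet`` is the uncorrected sensor reading (wet mole fraction).
    ``ledger`` carries the simulator's molar bookkeeping (µmol of CO₂, O₂,
    N₂+Ar, H₂O per sample) when produced by :func:`simulate_cycle`; it is
    ground truth for tests, never an input to the processing chain.
    """

    t_s: np.ndarray
    co2_ppm: np.ndarray
    o2_ppm_wet: np.ndarray
    rh_pct: np.ndarray
    temp_C: np.ndarray
    pressure_kPa: np.ndarray
    chamber: ChamberSpec
    start_time: pd.Timestamp
    cycle_id: str = ""
    ledger: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.t_s, self.co2_ppm, self.o2_ppm_wet,
                   self.rh_pct, self.temp_C, self.pressure_kPa)]
        n = arrays[0].size
        if any(a.size != n for a in arrays) or n == 0:
            raise ValueError("cycle vectors must be equal-length, non-empty")
        if np.any(np.diff(arrays[0]) <= 0):
            raise ValueError("t_s must be strictly increasing")
        for a in arrays[1:3]:
            if np.any(a <= 0) or np.any(a >= 1e6):
                raise ValueError("mole fractions must lie in (0, 1e6) ppm")
        (self.t_s, self.co2_ppm, self.o2_ppm_wet,
         self.rh_pct, self.temp_C, self.pressure_kPa) = arrays

    def subset(self, mask: np.ndarray) -> "RawCycle":
        ledger = self.ledger.loc[mask].reset_index(drop=True) \
            if self.ledger is not None else None
        return RawCycle(self.t_s[mask], self.co2_ppm[mask],
                        self.o2_ppm_wet[mask], self.rh_pct[mask],
                        self.temp_C[mask], self.pressure_kPa[mask],
                        self.chamber, self.start_time, self.cycle_id, ledger)

    def to_frame(self) -> pd.DataFrame:
        ts = self.start_time + pd.to_timedelta(self.t_s, unit="s")
        return pd.DataFrame({
            "timestamp_iso": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "tree_id": self.chamber.tree_id,
            "treatment": self.chamber.treatment,
            "cycle_id": self.cycle_id,
            "t_s": self.t_s,
            "co2_ppm": self.co2_ppm,
            "o2_ppm_wet": self.o2_ppm_wet,
            "rh_pct": self.rh_pct,
            "temp_C": self.temp_C,
            "pressure_kPa": self.pressure_kPa,
        })


@dataclass(frozen=True)
class SubstrateMix:
    """Respired-carbon source: lipid share, age, endmember signatures."""

    f_lipid: float = 0.0
    age_years: float = 0.0
    d13c_carb: float = D13C_CARB_DEFAULT
    d13c_lipid: float = D13C_LIPID_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_lipid <= 1.0):
            raise ValueError("f_lipid must lie in [0, 1]")
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    @property
    def d13c(self) -> float:
        """Flux-weighted source δ¹³C of the respired CO₂ (‰)."""
        return (self.f_lipid * self.d13c_lipid
                + (1.0 - self.f_lipid) * self.d13c_carb)

    @property
    def rq(self) -> float:
        """Respiratory quotient implied by the mixture."""
        return (CONSTANTS.rq_carb
                - (CONSTANTS.rq_carb - CONSTANTS.rq_lipid) * self.f_lipid)


@dataclass
class OROImage:
    """RGB raster of an Oil-Red-O-stained section with physical scale."""

    pixels: np.ndarray
    um_per_px: float
    true_coverage_pct: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H×W×3 RGB raster")
        if self.pixels.size == 0:
            raise ValueError("raster must be non-empty")
        if self.true_coverage_pct is not None and not (
                0.0 <= self.true_coverage_pct <= 100.0):
            raise ValueError("coverage must lie in 0–100%")

    def save(self, path) -> None:
        """Write the raster as PNG plus a sidecar CSV with the scale."""
        from PIL import Image
        path = Path(path)
        Image.fromarray(self.pixels).save(path)
        sidecar = path.with_suffix(".scale.csv")
        pd.DataFrame({"um_per_px": [self.um_per_px],
                      "true_coverage_pct": [self.true_coverage_pct]}
                     ).to_csv(sidecar, index=False)

    @classmethod
    def load(cls, path) -> "OROImage":
        from PIL import Image
        path = Path(path)
        pixels = np.asarray(Image.open(path).convert("RGB"))
        meta = pd.read_csv(path.with_suffix(".scale.csv"))
        truth = meta["true_coverage_pct"].iloc[0]
        return cls(pixels, float(meta["um_per_px"].iloc[0]),
                   None if pd.isna(truth) else float(truth))


# ---------------------------------------------------------------------------
# chamber cycles


def simulate_cycle(config: SimulationConfig, chamber: ChamberSpec,
                   env: EnvState, *, start_time="2018-07-05 00:00:00",
                   cycle_id: str = "c000", rng: np.random.Generator | None = None,
                   drift_offset_ppm: float = 0.0,
                   ambient_co2_ppm: float = AMBIENT_CO2_PPM,
                   ambient_o2_ppm: float = AMBIENT_O2_PPM) -> RawCycle:
    """Simulate the closed phase of one measurement cycle.

    The headspace starts at ambient composition (complete flush assumed)
    and the listed molar exchanges are integrated on the 10-s grid; water
    vapor is clamped at Magnus saturation.  Temperature and pressure are
    held constant within the cycle.  Gaussian sensor noise is applied to
    the CO₂ and wet-O₂ readings; ``drift_offset_ppm`` adds a constant
    CO₂-sensor offset (campaign-level drift).  Deterministic for a given
    seed/rng.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = float(config.sample_interval_s)
    t = np.arange(0.0, config.cycle_closed_s + dt / 2, dt)
    n_steps = t.size

    T_K = celsius_to_kelvin(env.temp_C)
    e_sat_kpa = float(magnus_saturation_vp_hpa(env.temp_C)) / 10.0
    x_h2o_sat = e_sat_kpa / env.pressure_kPa
    # total headspace content (µmol) from the gas law at closure
    n_tot0 = (env.pressure_kPa * chamber.volume_cm3 * 1e-6
              / (CONSTANTS.R_gas * T_K)) * 1e6

    x_h2o0 = (env.rh_pct / 100.0) * x_h2o_sat
    n_co2 = ambient_co2_ppm / 1e6 * n_tot0
    n_o2 = ambient_o2_ppm / 1e6 * n_tot0
    n_h2o = x_h2o0 * n_tot0
    n_inert = n_tot0 - n_co2 - n_o2 - n_h2o
    if n_inert <= 0:
        raise ValueError("ambient composition leaves no inert matrix")

    a = config.resp_flux * chamber.area_m2 * dt          # µmol CO2 per step
    b = a / config.rq_true                               # µmol O2 per step
    w = config.evap_rate * chamber.area_m2 * dt          # µmol H2O per step

    cols = {k: np.empty(n_steps) for k in
            ("n_co2", "n_o2", "n_h2o", "n_inert", "n_tot")}
    for i in range(n_steps):
        if i > 0:
            n_co2 += a
            n_o2 -= b
            if n_o2 <= 0:
                raise ValueError("headspace O2 exhausted; shorten the cycle")
            n_tot = n_co2 + n_o2 + n_h2o + n_inert
            # evaporation stalls once the headspace is saturated
            sat_cap = x_h2o_sat * (n_co2 + n_o2 + n_inert) / (1 - x_h2o_sat)
            n_h2o = min(n_h2o + w, max(sat_cap, n_h2o))
        n_tot = n_co2 + n_o2 + n_h2o + n_inert
        cols["n_co2"][i] = n_co2
        cols["n_o2"][i] = n_o2
        cols["n_h2o"][i] = n_h2o
        cols["n_inert"][i] = n_inert
        cols["n_tot"][i] = n_tot

    ledger = pd.DataFrame(cols)
    n_tot_t = ledger["n_tot"].to_numpy()
    co2 = ledger["n_co2"].to_numpy() / n_tot_t * 1e6
    o2 = ledger["n_o2"].to_numpy() / n_tot_t * 1e6
    x_h2o = ledger["n_h2o"].to_numpy() / n_tot_t
    rh = np.minimum(x_h2o / x_h2o_sat * 100.0, 100.0)

    co2 = co2 + drift_offset_ppm
    if config.noise_sd_co2 > 0:
        co2 = co2 + rng.normal(0.0, config.noise_sd_co2, n_steps)
    if config.noise_sd_o2 > 0:
        o2 = o2 + rng.normal(0.0, config.noise_sd_o2, n_steps)

    return RawCycle(
        t_s=t, co2_ppm=co2, o2_ppm_wet=o2, rh_pct=rh,
        temp_C=np.full(n_steps, env.temp_C),
        pressure_kPa=np.full(n_steps, env.pressure_kPa),
        chamber=chamber, start_time=pd.Timestamp(start_time),
        cycle_id=cycle_id, ledger=ledger)


def diel_temperature(hour: float, mean_C: float, amplitude_C: float) -> float:
    """Sinusoidal diel air temperature peaking at 15:00 local time."""
    return mean_C + amplitude_C * np.sin(2 * np.pi * (hour - 9.0) / 24.0)


def simulate_campaign(config: SimulationConfig, chambers: list[ChamberSpec],
                      n_days: int, *, start_time="2018-07-05 00:00:00",
                      env: EnvState | None = None,
                      rq_by_hour=None) -> list[RawCycle]:
    """Back-to-back 45+15-min cycles over ``n_days`` for each chamber.

    Cycle starts sit on a regular hourly grid; air temperature follows the
    configured diel sinusoid; the optional CO₂-sensor drift accumulates
    linearly with elapsed time.  Each chamber receives an independent
    noise stream spawned from the campaign seed.  ``rq_by_hour``, if
    given, maps the local hour (0–23) to the respiratory quotient of that
    cycle — a hook for diel substrate or refixation dynamics.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if env is None:
        env = EnvState()
    base = pd.Timestamp(start_time)
    cycle_len_s = config.cycle_closed_s + config.cycle_flush_s
    n_cycles = int(n_days * 86400 // cycle_len_s)
    mean_C, amp_C = config.diel_temp

    streams = np.random.SeedSequence(config.seed).spawn(len(chambers))
    cycles: list[RawCycle] = []
    for chamber, ss in zip(chambers, streams):
        rng = np.random.default_rng(ss)
        for k in range(n_cycles):
            t0 = base + pd.Timedelta(seconds=k * cycle_len_s)
            hour = t0.hour + t0.minute / 60.0
            cfg = config
            if rq_by_hour is not None:
                cfg = replace(config, rq_true=float(rq_by_hour(hour)))
            cyc_env = EnvState(
                temp_C=float(diel_temperature(hour, mean_C, amp_C)),
                pressure_kPa=env.pressure_kPa, rh_pct=env.rh_pct)
            drift = config.drift_ppm_per_day * (k * cycle_len_s / 86400.0)
            cycles.append(simulate_cycle(
                cfg, chamber, cyc_env, start_time=t0,
                cycle_id=f"{chamber.tree_id}-c{k:04d}", rng=rng,
                drift_offset_ppm=drift))
    return cycles


# ---------------------------------------------------------------------------
# flask samples and the atmospheric record


def make_linear_atmosphere(start_year: int, start_value: float,
                           annual_decline: float,
                           n_years: int) -> AtmosphereRecord:
    """Atmospheric Δ¹⁴C record declining linearly from a start year.

    value(y) = start_value − annual_decline · (y − start_year); the default
    post-bomb decline in this package is 4.7 ‰ yr⁻¹.
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    years = np.arange(start_year, start_year + n_years, dtype=float)
    return AtmosphereRecord(years, start_value - annual_decline
                            * (years - start_year))


def simulate_flask(mix: SubstrateMix, atmosphere: AtmosphereRecord,
                   sampling_year: float, accumulated_co2_ppm: float = 1000.0,
                   tree_id: str = "T1", treatment: str = "control",
                   *, observed: bool = False,
                   ca_ppm: float = AMBIENT_CO2_PPM,
                   da_permil: float = AMBIENT_D13C) -> FlaskSample:
    """Simulate one incubation flask fed by a known substrate mixture.

    The flask's δ¹³C is the flux-weighted mix of the endmember signatures
    (no kinetic fractionation at the source) and its Δ¹⁴C is the
    atmospheric value of the fixation year (radioactive decay over a few
    decades is negligible).  With ``observed=True`` the reported δ¹³C is
    instead the flask *measurement*: ambient air plus respired CO₂ mixed
    by mass balance with diffusive fractionation, i.e. exactly what the
    Davidson correction is designed to invert.
    """
    fixation_year = sampling_year - mix.age_years
    d14c = atmosphere(fixation_year)  # raises outside the record
    d13c = mix.d13c
    if observed:
        d13c = flask_observed_d13c(d13c, accumulated_co2_ppm,
                                   ca_ppm=ca_ppm, da_permil=da_permil)
    return FlaskSample(cs_ppm=accumulated_co2_ppm, d13c_raw=d13c,
                       D14C=d14c, date=sampling_year,
                       tree_id=tree_id, treatment=treatment)


def flask_observed_d13c(d13c_source: float, cs_ppm: float,
                        ca_ppm: float = AMBIENT_CO2_PPM,
                        da_permil: float = AMBIENT_D13C) -> float:
    """Forward measurement model for a flask δ¹³C reading.

    Mass balance of ambient CO₂ (Ca, δa) and accumulated respired CO₂
    (Cs − Ca, source δ) with the diffusive shift and kinetic factor of the
    Davidson convention applied to the respired component.
    """
    if cs_ppm <= ca_ppm:
        raise ValueError("flask CO2 must exceed ambient")
    s, k = CONSTANTS.davidson_shift, CONSTANTS.davidson_factor
    return (k * d13c_source * (cs_ppm - ca_ppm)
            + ca_ppm * (da_permil - s)) / cs_ppm + s


# ---------------------------------------------------------------------------
# stained-section images

BACKGROUND_RGB = (236, 224, 206)   # pale unstained wood
DROPLET_RGB = (198, 32, 46)        # Oil-Red-O droplet


def simulate_oro_image(true_coverage_pct: float,
                       droplet_radius_um: tuple[float, float] = (10.0, 40.0),
                       um_per_px: float = 2.0,
                       size_px: tuple[int, int] = (1500, 500),
                       seed: int = 0) -> OROImage:
    """Render a synthetic Oil-Red-O section with known droplet coverage.

    Non-overlapping red disks with radii uniform in ``droplet_radius_um``
    are placed on a pale background until the realized pixel coverage is
    within 0.02 percentage points of the target; the realized fraction is
    recorded as ground truth.  Raises if the target is unreachable
    (packing limit) — targets are restricted to at most 50%.
    """
    if not (0.0 <= true_coverage_pct <= 50.0):
        raise ValueError("target coverage must lie in 0–50%")
    w, h = size_px
    r_lo = max(droplet_radius_um[0] / um_per_px, 1.0)
    r_hi = max(droplet_radius_um[1] / um_per_px, r_lo)
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=bool)
    n_px = mask.size
    target_px = true_coverage_pct / 100.0 * n_px
    tol_px = 0.02 / 100.0 * n_px

    misses = 0
    while target_px - mask.sum() > tol_px:
        remaining = target_px - mask.sum()
        # shrink the last droplets so a single disk cannot overshoot; if even
        # the smallest admissible droplet overshoots, the target is unreachable
        r_fit = np.sqrt((remaining + tol_px) / np.pi)
        if r_fit < r_lo:
            raise ValueError(
                f"cannot reach {true_coverage_pct}% within tolerance: "
                "minimum droplet size overshoots the target")
        r = min(rng.uniform(r_lo, r_hi), r_fit)
        ri = int(np.ceil(r))
        cx = rng.integers(ri, w - ri) if w > 2 * ri else ri
        cy = rng.integers(ri, h - ri) if h > 2 * ri else ri
        yy, xx = np.ogrid[-ri:ri + 1, -ri:ri + 1]
        disk = (xx * xx + yy * yy) <= r * r
        sl = (slice(cy - ri, cy + ri + 1), slice(cx - ri, cx + ri + 1))
        if mask[sl][disk].any():
            misses += 1
            if misses > 20000:
                raise ValueError(
                    f"cannot reach {true_coverage_pct}% coverage: packing limit")
            continue
        patch = mask[sl].copy()
        patch[disk] = True
        mask[sl] = patch

    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[...] = BACKGROUND_RGB
    pixels[mask] = DROPLET_RGB
    realized = mask.sum() / n_px * 100.0
    return OROImage(pixels, um_per_px, realized)


# ---------------------------------------------------------------------------
# CSV writers / readers (sensor-log and flask schemas)


def cycles_to_csv(cycles: list[RawCycle], path) -> None:
    pd.concat([c.to_frame() for c in cycles], ignore_index=True).to_csv(
        path, index=False)


def cycles_from_csv(path) -> list[RawCycle]:
    """Rebuild RawCycle objects from a sensor-log CSV.

    Chamber geometry is not part of the log schema, so the returned cycles
    carry default geometry; pass explicit ChamberSpec objects downstream
    when volumes differ.
    """
    df = pd.read_csv(path)
    cycles = []
    for (tree, treat, cid), g in df.groupby(
            ["tree_id", "treatment", "cycle_id"], sort=False):
        g = g.sort_values("t_s")
        chamber = ChamberSpec(tree_id=str(tree), treatment=str(treat))
        cycles.append(RawCycle(
            g["t_s"].to_numpy(), g["co2_ppm"].to_numpy(),
            g["o2_ppm_wet"].to_numpy(), g["rh_pct"].to_numpy(),
            g["temp_C"].to_numpy(), g["pressure_kPa"].to_numpy(),
            chamber, pd.Timestamp(g["timestamp_iso"].iloc[0]), str(cid)))
    return cycles


def flasks_to_csv(samples: list[FlaskSample], path) -> None:
    pd.DataFrame([{
        "tree_id": s.tree_id, "treatment": s.treatment, "date": s.date,
        "cs_ppm": s.cs_ppm, "d13c_permil": s.d13c_raw,
        "D14C_permil": s.D14C,
    } for s in samples]).to_csv(path, index=False)
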