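# Methods

## Chamber model

The simulator treats the chamber headspace as a well-mixed reservoir of
CO₂, O₂, H₂O and an inert N₂+Ar remainder at constant temperature and
pressure within one 45-min closed cycle (diel variation is applied
between cycles; the chambers are small — ~100 cm³ on 0.0028 m² of stem —
so within-cycle thermal drift is a second-order effect). The initial
content is ambient air (400 ppm CO₂, 209,500 ppm O₂, water vapor from the
ambient RH via the Magnus relation, e_sat = 6.112·exp(17.62·T/(243.12+T))
hPa); a complete flush back to ambient is assumed between cycles. Each
10-s step the stem adds `resp_flux·A·Δt` µmol CO₂, removes
`resp_flux/rq_true·A·Δt` µmol O₂ and evaporates `evap_rate·A·Δt` µmol
H₂O, with water clamped at Magnus saturation. Sensors report wet mole
fractions (component over total moles), so the O₂ reading embeds the
dilution signal the processing chain must remove; Gaussian noise and an
optional linear drift are applied to the readings, never to the molar
ledger, which is retained as ground truth for tests.

Default study conditions: efflux 2 µmol m⁻² s⁻¹ (a typical mid-season
stem value; girdled trees are simulated at 1), RQ 1.0 for
carbohydrate-fed control stems vs 0.7 for lipid-fed girdled stems,
sensor noise 2 ppm on both gases, diel temperature 15 ± 5 °C peaking at
15:00, ambient RH 70%. Bark evaporation defaults to 0.5 µmol m⁻² s⁻¹,
chosen so chamber RH rises appreciably within a cycle (exercising the
dilution correction) without reaching saturation at the default
environment.

## O₂ dilution correction

Because O₂ is ~21% of the headspace, its mole fraction moves when any
component's molar amount changes. The only component the chamber neither
adds nor removes is the inert matrix, so the package corrects O₂ by
referencing it to that matrix and rescaling to the initial headspace:

    o2_corr(t) = o2(t) · M_ref / M(t),   M = 10⁶ − co2 − h2o − o2  [ppm]

The time derivative of `o2_corr` is then exactly the molar O₂ exchange
rate per initial headspace mole — the same basis on which the trace CO₂
slope is read — so the slope ratio (ARQ) and the gas-law flux conversion
are unbiased. Formulations that reference O₂ to a matrix containing O₂
itself (dividing by 1 − x_CO2 − x_H2O alone) leave a scale error of
x_N2/(x_N2+x_O2)² ≈ 0.80 on the O₂ slope and would inflate ARQ by ~25%;
the recovery tests against the simulator's molar ledger pin this down.
In `process_cycle` the CO₂ series is referenced to the same matrix: for a
trace gas this is a second-order refinement (≈5·10⁻⁴ relative at default
conditions) but it makes the noise-free ARQ recovery exact to three
decimals across the RQ range.

## Slope fitting, QC and aggregation

Slopes are ordinary least squares of concentration on time over the
half-open window [300 s, 1500 s) — the first 5 min after closure are
discarded against pressure transients, the following 20 min keep the
accumulation in its linear range (120 points at 10-s cadence). A
constant series is reported as slope 0 with R² = 0 so QC fails it rather
than erroring. Screens: R² ≥ 0.96 applied to each gas separately (the
conservative reading of a single-threshold rule), mean fit-window
RH ≤ 99% (the mean is robust to single-sample spikes; the statistic is
configurable), and sign sanity (CO₂ rising, corrected O₂ falling).
Thresholds are configuration with these defaults.

ARQ outliers are removed per tree by Tukey fences (Q1 − 1.5·IQR,
Q3 + 1.5·IQR; type-7 quantiles); with fewer than four values the screen
passes through with a warning flag. Gap filling linearly interpolates
runs of missing cycle-level values strictly shorter than 2 h on the
hourly cycle grid, flagging filled points and never extrapolating ends.
Aggregation averages into 6-h bins aligned at 00/06/12/18 local (phase
chosen at midnight; unstated in the field convention) and emits a daily
mean only when all four bins of the calendar day are populated.

## Isotope chain

Flask δ¹³C is corrected for ambient admixture with the Davidson mixing
equation, δ = (Cs(δs−4.4) − Ca(δa−4.4))/(1.0044(Cs−Ca)), with ambient
defaults Ca = 400 ppm and δa = −9‰. The simulator's `observed=True` mode
is the exact forward model of this correction (mass balance with the
diffusive shift on the respired component), so recovery is tested both
against that inverse and against a brute-force mixing construction.

Mean carbon age uses the quasi-linear post-bomb decline of atmospheric
Δ¹⁴C: age = (Δ¹⁴C_sample − Δ¹⁴C_atm(sampling year))/4.7‰ yr⁻¹. Annual
record values are treated as mid-growing-season points with linear
interpolation between them; lookups outside the record raise rather than
extrapolate. Radioactive decay between fixation and respiration is
neglected (< 0.7‰ over 60 y, below measurement noise). Negative ages are
clamped to zero and flagged. Samples more than 5‰ below the
contemporaneous atmosphere are screened as fossil-CO₂ contaminated; a
documented `mode="absolute"` switch instead screens below an absolute
5‰, since the field convention is ambiguous between the two readings.
Reported Δ¹⁴C is assumed already normalized to δ¹³C = −25‰ by the
laboratory.

Substrate partitioning inverts linear flux-weighted mixing between the
sugar (−27.11‰) and neutral-lipid (−31.14‰) endmembers; f_lipid is
clipped to [0, 1] with an out-of-range flag, and the implied ARQ
interpolates between the substrate quotients 1.0 and 0.7 at the same
fraction. No kinetic fractionation is applied at the source — endmember
signatures are treated as directly inherited by respired CO₂.

## Stained-section coverage

Droplets are detected by red dominance (R − max(G, B) > 50 on 8-bit
channels), adequate for the synthetic fixtures' saturated stain on a
pale background; the threshold is exposed because real slides need
tuning. ROIs are squares of 0.5 mm side (shape unspecified in the field
protocol; area 0.25 mm² fixed), placed independently and uniformly —
overlaps allowed — fully inside each of ten contiguous 3-mm bark→pith
sections, 50 per section. The estimate is the mean stained fraction over
all 500 ROIs. Fully-inside placement slightly under-weights border
pixels, so the estimator's exact expectation (enumerable with a
summed-area table) can differ from the whole-mask pixel fraction when
droplets are sparse; tests check unbiasedness against that enumeration
and closeness to the pixel fraction. The image generator places
non-overlapping disks until realized coverage is within 0.02 percentage
points of target, shrinking the final disks to land inside the
tolerance, and raises when the minimum droplet size or packing makes the
target unreachable; the realized pixel fraction is recorded as ground
truth.

## Pipeline and summaries

`run_pipeline` executes simulate → QC/flux/ARQ → gap-fill → aggregate →
isotopes → mixing → summaries in fixed order, writing CSVs plus a
manifest (config hash, seed, outputs); reruns with the same config are
bit-identical. Summaries are mean ± sample SD (n−1) on daily means by
default. Correlation is signed Pearson r on pairwise-complete pairs —
the package never reports a signed "r²". The default synthetic study is
6 chambers × 5 days, two treatments (RQ 1.0 vs 0.7, carbon ages 1 vs
10 y, lipid fractions 0 vs 1), sized to run in seconds while giving
15 complete tree-days per treatment.

## What the simulator does not emulate

No stem photosynthesis, axial CO₂ diffusion, xylem CO₂ transport or
local refixation: the simulated ARQ equals the metabolic RQ by
construction, so recovery tests validate the measurement chain, not the
ecophysiological interpretation of field ARQ. Sensor drift is linear
only; flushes are assumed complete; chamber T and P are constant within
a cycle; real Oil-Red-O slides have illumination gradients, stain
precipitates and out-of-focus regions the threshold model ignores.
Passing tests therefore demonstrate correctness of the estimators under
the stated measurement model, not robustness to every field artifact.
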