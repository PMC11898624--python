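"""Campaign processing: QC screening, outlier removal and aggregation.

Simulates two noisy chambers over two days, processes every cycle,
applies the R²/humidity/sign screens and the Tukey ARQ outlier fences,
and averages to 6-h bins and complete-24-h daily means.
"""

from stemresp import (ChamberSpec, SimulationConfig, aggregate_fluxes,
                      process_cycles, simulate_campaign)

config = SimulationConfig(resp_flux=2.0, rq_true=0.85, evap_rate=0.5,
                          noise_sd_co2=2.0, noise_sd_o2=2.0, seed=4)
chambers = [ChamberSpec(tree_id="T1"), ChamberSpec(tree_id="T2")]

cycles = simulate_campaign(config, chambers, n_days=2)
fluxes = process_cycles(cycles)
six_hour, daily = aggregate_fluxes(fluxes)

kept = int(fluxes["qc_overall"].sum())
print(f"cycles simulated  : {len(cycles)}")
print(f"cycles passing QC : {kept} ({100 * kept / len(cycles):.0f}%)")
print(f"ARQ outliers      : {int(fluxes['arq_outlier'].sum())}")
print("\ndaily means (complete 24-h days only):")
print(daily.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Daily-mean ARQ sits within a few thousandths of the true quotient 0.85;
# E_CO2 near 2.0 umol m-2 s-1 is the simulated efflux recovered per day.
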