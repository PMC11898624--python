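"""Flask isotope chain: Davidson correction, radiocarbon age, mixing.

Builds a linearly declining atmospheric Δ¹⁴C record (4.7 ‰ yr⁻¹),
simulates flask samples respiring 5-year-old carbon that is half lipid by
flux, and runs the analysis chain: fossil screening, Davidson δ¹³C
correction, bomb-radiocarbon mean age and two-endmember partitioning.
"""

from stemresp import SubstrateMix, make_linear_atmosphere, simulate_flask
from stemresp.isotopes import analyze_flasks

atmosphere = make_linear_atmosphere(1990, 120.0, 4.7, 40)
mix = SubstrateMix(f_lipid=0.5, age_years=5.0)

flasks = [simulate_flask(mix, atmosphere, 2021.5, cs_ppm, observed=True)
          for cs_ppm in (800.0, 1200.0, 2000.0)]
table = analyze_flasks(flasks, atmosphere)

cols = ["cs_ppm", "d13c_raw", "d13c_corrected", "D14C",
        "mean_age_years", "f_lipid", "expected_arq"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# The raw flask delta13C varies with accumulation (more ambient admixture at
# low Cs); the Davidson correction collapses all three onto the source
# signature -29.125 permil, giving f_lipid 0.5, expected ARQ 0.85 and a
# recovered mean carbon age of 5.0 years.
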