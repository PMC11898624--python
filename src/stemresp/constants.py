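"""Physical constants and field-convention defaults used across the package.

All defaults reflect the conventions of closed-chamber stem gas-exchange
work: the molar gas constant in chamber-friendly units, the Davidson
mixing-correction constants for flask δ¹³C, the mean annual decline of
atmospheric (post-bomb) Δ¹⁴C, assumed ambient-air composition, and the
canonical respiratory quotients of the two substrate classes.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysConstants:
    """Bundle of constants; instantiate to override any of them.

    Attributes
    ----------
    R_gas : molar gas constant, m³ kPa K⁻¹ mol⁻¹.
    davidson_shift : ‰, the diffusive-fractionation shift applied to both
        flask and ambient δ¹³C in the Davidson correction.
    davidson_factor : dimensionless kinetic-fractionation factor in the
        Davidson denominator.
    atm_decline : ‰ yr⁻¹, mean annual decline of atmospheric Δ¹⁴C over the
        post-bomb period used for mean-age estimation.
    ca_default : ppm, assumed ambient CO₂ mole fraction.
    da_default : ‰, assumed ambient δ¹³C of CO₂.
    rq_carb : respiratory quotient of carbohydrate oxidation.
    rq_lipid : respiratory quotient of lipid oxidation.
    """

    R_gas: float = 0.008314
    davidson_shift: float = 4.4
    davidson_factor: float = 1.0044
    atm_decline: float = 4.7
    ca_default: float = 400.0
    da_default: float = -9.0
    rq_carb: float = 1.0
    rq_lipid: float = 0.7

    def __post_init__(self) -> None:
        positive = ("R_gas", "davidson_shift", "davidson_factor",
                    "atm_decline", "ca_default", "rq_carb", "rq_lipid")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Default constants instance shared by the whole package.
CONSTANTS = PhysConstants()

# Ambient (flush) air composition assumed throughout unless configured.
AMBIENT_CO2_PPM = 400.0
AMBIENT_O2_PPM = 209_500.0
AMBIENT_D13C = -9.0


def celsius_to_kelvin(temp_C: float) -> float:
    return temp_C + 273.15
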