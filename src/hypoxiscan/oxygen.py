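"""Seawater dissolved-oxygen solubility and air-saturation conversions.

Dissolved O2 in experimental work on marine invertebrates is reported either
as a concentration (µmol L-1) or as percent air saturation (%AS), the
concentration relative to equilibrium with water-saturated air at the ambient
temperature, salinity and barometric pressure.  Converting between the two
requires the equilibrium solubility, which this module computes with the
Garcia & Gordon (1992) combined refit of the Benson & Krause data — the
per-litre (cm3 dm-3) variant, converted to µmol L-1 with the ideal molar
volume of O2.  Valid for oceanographic ranges, roughly -2..40 °C and
salinity 0..42.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OxygenConditions",
    "o2_saturation_uM",
    "percent_as_to_uM",
    "uM_to_percent_as",
]

# Garcia & Gordon (1992), combined fit, volumetric (cm3 dm-3) coefficients.
_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_C0 = -4.88682e-7

# Ideal-gas molar volume of O2 at STP (L mol-1), used to convert cm3 dm-3
# to µmol L-1.
_O2_MOLAR_VOLUME_L = 22.3916


@dataclass(frozen=True)
class OxygenConditions:
    """Water conditions that set the air-equilibrium O2 concentration.

    Parameters
    ----------
    temperature_c:
        Water temperature in °C; accepted range -2..40.
    salinity:
        Practical salinity (dimensionless); accepted range 0..42.
    pressure_atm:
        Barometric pressure in atm.  The solubility fit is referenced to
        1 atm moist air; saturation scales linearly with pressure.
    """

    temperature_c: float
    salinity: float
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature_c <= 40.0):
            raise ValueError(
                f"temperature {self.temperature_c} °C outside supported "
                "range [-2, 40]"
            )
        if not (0.0 <= self.salinity <= 42.0):
            raise ValueError(
                f"salinity {self.salinity} outside supported range [0, 42]"
            )
        if self.pressure_atm <= 0:
            raise ValueError("pressure must be positive")


def o2_saturation_uM(conditions: OxygenConditions) -> float:
    """Equilibrium dissolved O2 (µmol L-1) for water-saturated air.

    This is the concentration at 100% air saturation.  At 26 °C and
    salinity 32 it evaluates to ≈211.6 µM.
    """
    t = conditions.temperature_c
    s = conditions.salinity
    ts = math.log((298.15 - t) / (273.15 + t))  # scaled temperature
    ln_c = sum(a * ts**i for i, a in enumerate(_A))
    ln_c += s * sum(b * ts**i for i, b in enumerate(_B))
    ln_c += _C0 * s * s
    cm3_per_l = math.exp(ln_c)
    return cm3_per_l / _O2_MOLAR_VOLUME_L * 1000.0 * conditions.pressure_atm


def percent_as_to_uM(percent: float, conditions: OxygenConditions) -> float:
    """Convert percent air saturation to µmol L-1 dissolved O2."""
    if percent < 0:
        raise ValueError("percent air saturation must be >= 0")
    return percent / 100.0 * o2_saturation_uM(conditions)


def uM_to_percent_as(conc_uM: float, conditions: OxygenConditions) -> float:
    """Convert dissolved O2 in µmol L-1 to percent air saturation."""
    if conc_uM < 0:
        raise ValueError("O2 concentration must be >= 0")
    return conc_uM / o2_saturation_uM(conditions) * 100.0
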