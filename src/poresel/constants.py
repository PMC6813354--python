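"""Physical constants shared across the package.

All free energies are in kcal/mol, distances in Å, time in ns,
voltages in mV, concentrations in mol/L.
"""

from __future__ import annotations

import math

#: Gas constant in kcal/(mol·K).
R_KCAL: float = 1.987204259e-3

#: Simulation temperature (K) used throughout the simulation-side modules.
SIM_TEMPERATURE_K: float = 315.0

#: Avogadro's number (1/mol).
N_AVOGADRO: float = 6.02214076e23

#: Å³ -> L conversion.
LITERS_PER_CUBIC_ANGSTROM: float = 1e-27

#: Å³ -> M⁻¹ conversion factor (N_A · 10⁻²⁷).
ANGSTROM3_TO_PER_MOLAR: float = N_AVOGADRO * LITERS_PER_CUBIC_ANGSTROM

#: Faraday constant, C/mol.
FARADAY_C_PER_MOL: float = 96485.33212

#: Gas constant in J/(mol·K), for the electrochemical thermal voltage.
R_JOULE: float = 8.314462618

#: Thermal voltage RT/F in mV used for relative permeabilities
#: (room-temperature experiments; 25.4 mV as conventionally quoted).
THERMAL_MV_ROOM: float = 25.4


def kBT(temperature: float = SIM_TEMPERATURE_K) -> float:
    """Thermal energy k_B·T in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def thermal_voltage_mv(temperature: float = 295.0) -> float:
    """Thermal voltage RT/F in mV at ``temperature`` (K).

    At room temperature (~295 K) this is 25.4 mV to three significant
    figures, the constant used when converting reversal-potential shifts
    into permeability ratios.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_JOULE * temperature / FARADAY_C_PER_MOL * 1e3


def boltzmann_factor(energy_kcal: float, temperature: float = SIM_TEMPERATURE_K) -> float:
    """exp(−E/k_BT) for an energy in kcal/mol."""
    return math.exp(-energy_kcal / kBT(temperature))
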