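"""Physical constants and thermal-voltage helpers.

Units follow the package-wide convention: millivolts, milliseconds,
picoamperes, millimolar.  Energies are reported in kcal/mol, for which the
Faraday constant is taken as 23.061 kcal mol^-1 V^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Faraday constant in kcal mol^-1 V^-1 (used for gating energies).
F_KCAL_PER_MOL_V = 23.061

#: Faraday constant in C mol^-1.
F_C_PER_MOL = 96485.33212

#: Molar gas constant in J mol^-1 K^-1.
R_J_PER_MOL_K = 8.31446261815324

#: Default absolute temperature (22 degrees C).
T_K_DEFAULT = 295.15


def celsius_to_kelvin(temperature_C: float) -> float:
    return temperature_C + 273.15


def thermal_voltage_mV(T_K: float = T_K_DEFAULT) -> float:
    """RT/F in millivolts (~25.43 mV at 22 degrees C)."""
    return 1000.0 * R_J_PER_MOL_K * T_K / F_C_PER_MOL


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the constants entering Boltzmann and energy expressions."""

    F_kcal: float = F_KCAL_PER_MOL_V
    F_C: float = F_C_PER_MOL
    R: float = R_J_PER_MOL_K
    T_K: float = T_K_DEFAULT

    @property
    def rt_over_f_mV(self) -> float:
        return 1000.0 * self.R * self.T_K / self.F_C
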