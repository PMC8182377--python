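"""Physical constants and default experimental conditions.

All thermodynamic energies are in kcal/mol; temperatures in kelvin
internally (public APIs that take Celsius say so); NMR interaction
constants in SI (rad/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: Default analysis temperature (25 degC), K.
T_DEFAULT = 298.15

#: RT at 25 degC, kcal/mol.
RT_DEFAULT = R_KCAL * T_DEFAULT

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8

#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative).
GAMMA_N = -2.7126e7

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: mu0 / 4 pi, T^2 J^-1 m^3.
MU0_OVER_4PI = 1.0e-7


def field_from_proton_mhz(mhz: float) -> float:
    """Static field B0 (tesla) for a given 1H Larmor frequency in MHz."""
    return 2.0 * np.pi * mhz * 1e6 / GAMMA_H


@dataclass(frozen=True)
class PhysicalConstants:
    """Interaction constants for 15N amide relaxation.

    Parameters
    ----------
    rNH : N-H bond length, angstrom.
    dCSA : 15N chemical shift anisotropy, ppm.
    field : static magnetic field, tesla.  The default corresponds to a
        1H Larmor frequency of 850 MHz.
    """

    rNH: float = 1.02
    dCSA: float = -160.0
    field: float = field_from_proton_mhz(850.0)

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency, rad/s (signed)."""
        return GAMMA_H * self.field

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency, rad/s (signed, negative)."""
        return GAMMA_N * self.field

    @property
    def d(self) -> float:
        """Dipolar interaction constant, rad/s."""
        r_m = self.rNH * 1e-10
        return MU0_OVER_4PI * HBAR * GAMMA_H * GAMMA_N / r_m**3

    @property
    def c(self) -> float:
        """CSA interaction constant, rad/s."""
        return self.omega_n * self.dCSA * 1e-6 / np.sqrt(3.0)
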