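"""Unit and physical-constant conventions used across the package.

Everything internal is kcal/mol, Å, fs, Kelvin, elementary charges, Debye and
MV/cm.  All constants are derived from CODATA values via :mod:`scipy.constants`
so unit conversions are never hard-coded silently.
"""

import scipy.constants as _c

#: gas constant in kcal/mol/K (thermochemical calorie, 4184 J/kcal)
R_KCAL = _c.R / 4184.0

#: Hartree in kcal/mol
KCAL_PER_HARTREE = _c.physical_constants["Hartree energy"][0] * _c.N_A / 4184.0

#: 1 Debye in C·m (exact: 1e-21 / c)
DEBYE_SI = 1e-21 / _c.c

#: 1 e·Å expressed in Debye
DEBYE_PER_E_ANGSTROM = _c.e * 1e-10 / DEBYE_SI

#: Coulomb field prefactor: field in MV/cm at r Å from charge q e is
#: COULOMB_MV_CM * q / r**2   (1 MV/cm = 1e8 V/m)
COULOMB_MV_CM = _c.e / (4.0 * _c.pi * _c.epsilon_0) / 1e-20 / 1e8

#: interaction energy of 1 Debye with 1 MV/cm, in kcal/mol
DIPOLE_FIELD_KCAL = DEBYE_SI * 1e8 * _c.N_A / 4184.0


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return R_KCAL * temperature


def hartree_to_kcal(value: float) -> float:
    return value * KCAL_PER_HARTREE
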