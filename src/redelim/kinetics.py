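"""Transition-state-theory rate comparisons and unit-conversion derivations."""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._units import DIPOLE_FIELD_KCAL, R_KCAL
from .exceptions import ParameterError


def tst_acceleration(dg_uncat: float, dg_cat: float, temperature: float = 298.15) -> float:
    """Rate acceleration exp(ΔΔG‡ / RT) from two activation free energies.

    ΔΔG‡ = dg_uncat − dg_cat in kcal/mol; RT ≈ 0.5925 kcal/mol at 298.15 K.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    return math.exp((dg_uncat - dg_cat) / (R_KCAL * temperature))


def dipole_field_energy_constant() -> float:
    """Interaction energy of 1 Debye with 1 MV/cm, in kcal/mol.

    Derived from CODATA constants ((1 D)·(1 MV/cm)·N_A / 4184 J/kcal);
    ≈ 0.048 kcal/mol per Debye·MV/cm.
    """
    return DIPOLE_FIELD_KCAL


@dataclass(frozen=True)
class RateComparison:
    """Barriers (kcal/mol), temperature and the implied TST acceleration."""

    dg_uncat: float
    dg_cat: float
    temperature: float
    acceleration: float

    def to_dict(self) -> dict:
        return {
            "dg_uncatalyzed_kcal_mol": self.dg_uncat,
            "dg_catalyzed_kcal_mol": self.dg_cat,
            "temperature_K": self.temperature,
            "acceleration": self.acceleration,
        }


def compare_rates(dg_uncat: float, dg_cat: float,
                  temperature: float = 298.15) -> RateComparison:
    return RateComparison(
        dg_uncat=dg_uncat,
        dg_cat=dg_cat,
        temperature=temperature,
        acceleration=tst_acceleration(dg_uncat, dg_cat, temperature),
    )
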