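"""Unit systems for the bead-model engine.

Two conventions are supported:

* ``REDUCED`` — the engine default: kB = 1, unit mass, unit length.  All toy
  landscapes and the adaptive-sampling fixtures live here; a temperature of
  1.0 means the thermal energy equals one energy unit.
* ``PHYSICAL`` — an AKMA-like convention (Å, kcal/mol, ps, amu, Kelvin) used
  where numbers are compared against laboratory-scale quantities: the
  targeted-MD schedule (Å/ns rates), ion-count box arithmetic, and manifest
  bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnitSystem:
    """A self-consistent set of mechanical units.

    Attributes
    ----------
    name : str
        Identifier ("reduced" or "physical").
    kB : float
        Boltzmann constant in energy units per Kelvin-analog.
    acc_factor : float
        Conversion so that acceleration = acc_factor * force / mass.
        1 kcal/mol = 418.4 amu Å²/ps², hence 418.4 in physical units.
    """

    name: str
    kB: float
    acc_factor: float

    def thermal_energy(self, temperature: float) -> float:
        return self.kB * temperature


#: Dimensionless engine units (kB = 1).
REDUCED = UnitSystem("reduced", 1.0, 1.0)

#: Å / kcal·mol⁻¹ / ps / amu / K.
PHYSICAL = UnitSystem("physical", 1.987204259e-3, 418.4)

#: Avogadro constant, mol⁻¹ (used by the ion-count arithmetic).
AVOGADRO = 6.02214076e23

#: Cubic ångström in litres.
A3_TO_L = 1e-27
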