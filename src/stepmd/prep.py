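"""System-setup arithmetic: simulation cells and ion counts.

Physical-unit helpers mirroring the solvated-box preparation of a large
nucleoprotein complex: given a cell and a target molarity, how many extra
divalent ions must be added beyond those already placed at functional sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .units import A3_TO_L, AVOGADRO

__all__ = ["SimulationCell", "ion_count_for_concentration", "concentration_for_count"]


@dataclass(frozen=True)
class SimulationCell:
    """Orthorhombic cell with edge lengths in Å."""

    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or any(x <= 0 for x in self.lengths):
            raise ValueError("cell needs three positive edge lengths")

    @property
    def volume(self) -> float:
        """Volume in Å³."""
        a, b, c = self.lengths
        return a * b * c

    @property
    def volume_litres(self) -> float:
        return self.volume * A3_TO_L


def ion_count_for_concentration(
    cell: SimulationCell, concentration: float, already_placed: int = 0
) -> int:
    """Extra ions needed to reach ``concentration`` (mol/L) in ``cell``.

    The total count is the nearest integer to c·V·N_A (one-ion quantization);
    the return value is the surplus over ``already_placed``, floored at zero.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if already_placed < 0:
        raise ValueError("already_placed must be non-negative")
    total = round(concentration * cell.volume_litres * AVOGADRO)
    return max(int(total) - int(already_placed), 0)


def concentration_for_count(cell: SimulationCell, n_ions: int) -> float:
    """Molarity (mol/L) corresponding to ``n_ions`` in ``cell``."""
    if n_ions < 0:
        raise ValueError("n_ions must be non-negative")
    return n_ions / (cell.volume_litres * AVOGADRO)
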