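"""Analytic single-particle energy landscapes.

Desk-scale stand-ins for a rugged conformational energy surface: a 1D double
well with a closed-form Boltzmann density (the oracle for accelerated-MD
reweighting) and the Müller–Brown surface with three known minima.

The particle moves on the landscape coordinates only; the unused Cartesian
coordinates are softly tethered to zero so that trajectories remain bounded
without periodic boundaries.
"""

from __future__ import annotations

import numpy as np

from .system import (
    AxisHarmonic,
    Landscape1D,
    MuellerBrown2D,
    ParticleSystem,
)
from .units import REDUCED

__all__ = ["make_analytic_landscape"]

#: Spring constant of the soft tether on unused coordinates.
_TETHER_K = 1.0


def make_analytic_landscape(
    kind: str,
    *,
    a: float = 1.0,
    b: float = 1.0,
    scale: float = 1.0,
    mass: float = 1.0,
) -> ParticleSystem:
    """Build a one-particle system on an analytic surface.

    Parameters
    ----------
    kind : {"double_well_1d", "mueller_brown_2d"}
        ``double_well_1d`` is V(x) = a·(x²−b)² with wells at ±√b and a
        barrier of a·b² at x = 0; ``mueller_brown_2d`` is the standard
        Müller–Brown surface times ``scale``.
    a, b : float
        Double-well shape parameters (barrier a·b² must be positive).
    scale : float
        Energy multiplier for the Müller–Brown surface.
    mass : float
        Particle mass.

    Returns
    -------
    ParticleSystem
        With the landscape term first in ``terms`` (so its analytic
        ``energy``/``gradient``/``boltzmann_density`` are reachable as
        ``system.terms[0]``).
    """
    if kind == "double_well_1d":
        if a <= 0 or b <= 0:
            raise ValueError("double_well_1d requires a > 0 and b > 0 (positive barrier)")
        terms = (
            Landscape1D(i=0, a=a, b=b),
            AxisHarmonic(i=0, axis=1, k=_TETHER_K, center=0.0),
            AxisHarmonic(i=0, axis=2, k=_TETHER_K, center=0.0),
        )
        name = "double_well_1d"
    elif kind == "mueller_brown_2d":
        if scale <= 0:
            raise ValueError("mueller_brown_2d requires scale > 0")
        terms = (
            MuellerBrown2D(i=0, scale=scale),
            AxisHarmonic(i=0, axis=2, k=_TETHER_K, center=0.0),
        )
        name = "mueller_brown_2d"
    else:
        raise ValueError(f"unknown landscape kind {kind!r}")
    return ParticleSystem(
        masses=np.array([mass]),
        terms=terms,
        units=REDUCED,
        name=name,
    )
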