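"""Particle systems: beads, potential terms, labels and groups.

A :class:`ParticleSystem` is the static description of a toy mechanical
model — masses, a list of potential terms, named sites (e.g. ``"scissile"``,
``"cat1"``) and named groups (e.g. ``"mobile_domain"``, ``"scaffold"``).
Dynamics and force evaluation live in :mod:`stepmd.engine`.

Potential terms
---------------
``HarmonicBond``     0.5·k·(|xi−xj| − r0)²
``PairWell``         short-range Gaussian attraction, −ε·exp(−(r−r0)²/2σ²),
                     shifted to zero at the cutoff
``AxisDoubleWell``   a·(u−x1)²·(u−x2)² − d·exp(−(u−p)²/2σ²) on one Cartesian
                     coordinate u of one bead (the docking coordinate)
``AxisHarmonic``     0.5·k·(u−c)² on one coordinate (lateral confinement)
``Anchor``           0.5·k·|x−ref|² positional tether (scaffold pinning)
``Landscape1D`` /    analytic single-particle energy surfaces used as
``MuellerBrown2D``   desk-scale oracles (see :mod:`stepmd.landscapes`)

Every term carries a ``channel`` — ``"internal"`` for the designated
internal-coordinate (double-well) terms that play the role of the dihedral
boost channel in dual-boost accelerated MD, ``"general"`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import REDUCED, UnitSystem

__all__ = [
    "HarmonicBond",
    "PairWell",
    "PairRepulsion",
    "AxisDoubleWell",
    "AxisHarmonic",
    "Anchor",
    "Landscape1D",
    "MuellerBrown2D",
    "ParticleSystem",
]


@dataclass(frozen=True)
class HarmonicBond:
    i: int
    j: int
    k: float
    r0: float
    channel: str = "general"


@dataclass(frozen=True)
class PairWell:
    """Short-range Gaussian attraction between beads ``i`` and ``j``.

    V(r) = −ε·[exp(−(r−r0)²/(2σ²)) − exp(−(cutoff−r0)²/(2σ²))] for r < cutoff,
    0 beyond.  The minimum sits at ``r0`` with depth ≈ ε (exactly ε minus the
    cutoff shift), which makes designed contact distances stationary points.
    """

    i: int
    j: int
    epsilon: float
    r0: float
    sigma: float
    cutoff: float
    channel: str = "general"

    def energy_at(self, r: float) -> float:
        if r >= self.cutoff:
            return 0.0
        g = math.exp(-((r - self.r0) ** 2) / (2.0 * self.sigma**2))
        gc = math.exp(-((self.cutoff - self.r0) ** 2) / (2.0 * self.sigma**2))
        return -self.epsilon * (g - gc)


@dataclass(frozen=True)
class PairRepulsion:
    """Steric wall between beads: 0.5·k·(r − r_wall)² for r < r_wall, else 0.

    Continuous with continuous force at the wall; models excluded volume at
    a designed contact distance.
    """

    i: int
    j: int
    k: float
    r_wall: float
    channel: str = "general"

    def energy_at(self, r: float) -> float:
        if r >= self.r_wall:
            return 0.0
        return 0.5 * self.k * (r - self.r_wall) ** 2


@dataclass(frozen=True)
class AxisDoubleWell:
    """Quartic double well on one coordinate of one bead.

    V(u) = a·(u−x1)²·(u−x2)² − depth·exp(−(u−deepen_at)²/(2·deepen_sigma²))

    Both ``x1`` and ``x2`` are exact minima of the quartic part; the optional
    Gaussian deepens one basin without displacing the stationary points
    appreciably (it is localized, σ ≪ |x1−x2|).
    """

    i: int
    axis: int
    x1: float
    x2: float
    a: float
    deepen_at: float = 0.0
    deepen_depth: float = 0.0
    deepen_sigma: float = 0.5
    channel: str = "internal"

    @property
    def barrier(self) -> float:
        """Quartic barrier height a·((x2−x1)/2)⁴ relative to the well floors."""
        b = 0.5 * abs(self.x2 - self.x1)
        return self.a * b**4


@dataclass(frozen=True)
class AxisHarmonic:
    i: int
    axis: int
    k: float
    center: float
    channel: str = "general"


@dataclass(frozen=True)
class Anchor:
    i: int
    k: float
    ref: tuple[float, float, float]
    channel: str = "general"


@dataclass(frozen=True)
class Landscape1D:
    """Analytic 1D double well V(x) = a·(x²−b)² acting on the x coordinate.

    Wells at x = ±√b, barrier top V(0) = a·b².  Exposes the analytic energy,
    gradient and Boltzmann density for use as test oracles.
    """

    i: int
    a: float
    b: float
    channel: str = "internal"

    @property
    def barrier(self) -> float:
        return self.a * self.b**2

    def energy(self, x: float) -> float:
        return self.a * (x**2 - self.b) ** 2

    def gradient(self, x: float) -> float:
        return 4.0 * self.a * x * (x**2 - self.b)

    def boltzmann_density(self, x: np.ndarray, temperature: float) -> np.ndarray:
        """Normalized equilibrium density exp(−V/kT)/Z on the given grid."""
        x = np.asarray(x, dtype=float)
        w = np.exp(-self.energy(x) / temperature)
        z = np.trapezoid(w, x)
        return w / z


# Standard Müller–Brown parameterization.
_MB_A = (-200.0, -100.0, -170.0, 15.0)
_MB_a = (-1.0, -1.0, -6.5, 0.7)
_MB_b = (0.0, 0.0, 11.0, 0.6)
_MB_c = (-10.0, -10.0, -6.5, 0.7)
_MB_x0 = (1.0, 0.0, -0.5, -1.0)
_MB_y0 = (0.0, 0.5, 1.5, 1.0)


@dataclass(frozen=True)
class MuellerBrown2D:
    """The Müller–Brown surface on the (x, y) coordinates of one bead.

    Three local minima near (−0.558, 1.442), (0.623, 0.028) and
    (−0.050, 0.467); ``scale`` multiplies the canonical energies (which span
    hundreds of units) down to thermally accessible values.
    """

    i: int
    scale: float = 1.0
    channel: str = "general"

    def energy(self, x: float, y: float) -> float:
        e = 0.0
        for A, a, b, c, x0, y0 in zip(_MB_A, _MB_a, _MB_b, _MB_c, _MB_x0, _MB_y0):
            dx, dy = x - x0, y - y0
            e += A * math.exp(a * dx * dx + b * dx * dy + c * dy * dy)
        return self.scale * e

    def gradient(self, x: float, y: float) -> tuple[float, float]:
        gx = gy = 0.0
        for A, a, b, c, x0, y0 in zip(_MB_A, _MB_a, _MB_b, _MB_c, _MB_x0, _MB_y0):
            dx, dy = x - x0, y - y0
            e = A * math.exp(a * dx * dx + b * dx * dy + c * dy * dy)
            gx += e * (2.0 * a * dx + b * dy)
            gy += e * (b * dx + 2.0 * c * dy)
        return self.scale * gx, self.scale * gy


Term = (
    HarmonicBond
    | PairWell
    | PairRepulsion
    | AxisDoubleWell
    | AxisHarmonic
    | Anchor
    | Landscape1D
    | MuellerBrown2D
)


@dataclass
class ParticleSystem:
    """Beads, masses, potential terms, named sites and groups.

    Parameters
    ----------
    masses : array of shape (n,)
        Per-particle masses, all > 0.
    terms : sequence of potential terms
        See module docstring for the available term types.
    site_labels : mapping name -> particle index
        Named sites such as "scissile", "cat1", "cat2", "fretA"…, "ion".
    groups : mapping name -> index sequence
        Named selections such as "mobile_domain" and "scaffold".
    units : UnitSystem
        REDUCED (default) or PHYSICAL.
    poses : mapping name -> (n, 3) coordinates
        Designed reference poses (e.g. "undocked", "docked") for fixtures.
    """

    masses: np.ndarray
    terms: tuple[Term, ...] = ()
    site_labels: dict[str, int] = field(default_factory=dict)
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    units: UnitSystem = REDUCED
    poses: dict[str, np.ndarray] = field(default_factory=dict)
    name: str = "system"

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.ndim != 1 or self.masses.size == 0:
            raise ValueError("masses must be a non-empty 1D array")
        if np.any(self.masses <= 0) or not np.all(np.isfinite(self.masses)):
            raise ValueError("masses must be positive and finite")
        self.terms = tuple(self.terms)
        n = self.n_particles
        for t in self.terms:
            for attr in ("i", "j"):
                idx = getattr(t, attr, None)
                if idx is not None and not (0 <= idx < n):
                    raise ValueError(f"term {t!r} references particle {idx} >= {n}")
            cut = getattr(t, "cutoff", None)
            if cut is not None and cut <= 0:
                raise ValueError("pair cutoffs must be positive")
        seen: set[str] = set()
        for label, idx in self.site_labels.items():
            if label in seen:
                raise ValueError(f"duplicate site label {label!r}")
            seen.add(label)
            if not (0 <= idx < n):
                raise ValueError(f"site label {label!r} -> {idx} out of range")
        self.groups = {
            g: np.asarray(sorted(set(int(i) for i in idxs)), dtype=int)
            for g, idxs in self.groups.items()
        }
        for g, idxs in self.groups.items():
            if idxs.size and (idxs.min() < 0 or idxs.max() >= n):
                raise ValueError(f"group {g!r} indices out of range")
        self.poses = {k: np.asarray(v, dtype=float) for k, v in self.poses.items()}
        for k, v in self.poses.items():
            if v.shape != (n, 3):
                raise ValueError(f"pose {k!r} has shape {v.shape}, expected {(n, 3)}")

    @property
    def n_particles(self) -> int:
        return int(self.masses.size)

    def site(self, label: str) -> int:
        try:
            return self.site_labels[label]
        except KeyError:
            raise KeyError(
                f"unknown site label {label!r}; known: {sorted(self.site_labels)}"
            ) from None

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(
                f"unknown group {name!r}; known: {sorted(self.groups)}"
            ) from None

    def without_terms(self, predicate) -> "ParticleSystem":
        """A copy of this system with every term matching ``predicate`` removed."""
        return ParticleSystem(
            masses=self.masses.copy(),
            terms=tuple(t for t in self.terms if not predicate(t)),
            site_labels=dict(self.site_labels),
            groups={g: v.copy() for g, v in self.groups.items()},
            units=self.units,
            poses={k: v.copy() for k, v in self.poses.items()},
            name=self.name,
        )
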