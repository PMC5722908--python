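"""Synthetic domain-docking fixture.

A bead model emulating a nuclease-domain docking transition: a pinned
*scaffold* (the protein body plus nucleic-acid analog, carrying the scissile
site and two labeled reporter sites) and a rigid-ish *mobile domain* (the
nuclease-domain analog, carrying two catalytic sites and a third reporter
site) tethered to the scaffold by two flexible linkers.  The mobile domain's
height above the scissile site is governed by a double-well docking
coordinate with an *undocked* basin (progress metric ≈ 9 length units) and a
*docked* basin (≈ 6), echoing the ~9 Å → ~6 Å geometric-mean transition the
toolkit's adaptive protocol is designed to capture.

A removable ion bead bridges the two catalytic sites and the scissile site
through short-range attractions.  Without the ion the undocked basin is the
deeper one and the docked pose is only marginally metastable; with the ion
the docked pose becomes the global minimum — the fixture analog of a
catalytic metal that is indispensable for the active state.

The designed poses ("undocked", "docked") are exact stationary points of
their respective basins by construction, so the progress metric evaluated on
the constructed coordinates equals the designed value to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .system import (
    Anchor,
    AxisDoubleWell,
    AxisHarmonic,
    HarmonicBond,
    PairRepulsion,
    PairWell,
    ParticleSystem,
)
from .units import PHYSICAL, REDUCED, UnitSystem

__all__ = ["DockingGeometry", "make_domain_docking_model", "make_tmd_docking_setup"]


@dataclass(frozen=True)
class DockingGeometry:
    """Pose and stiffness parameters of the docking fixture.

    Lengths are in engine length units (Å in physical mode); energies are in
    units of the thermal energy at the reference temperature times
    ``energy_scale`` (so with ``energy_scale = kB·T_ref`` the same landscape
    is expressed in kcal/mol).

    The progress metric is the geometric mean of the scissile–cat1 and
    scissile–cat2 distances; ``undocked_metric``/``docked_metric`` are its
    designed values in the two poses and must satisfy
    ``undocked_metric > docked_metric > lateral_offset``.
    """

    undocked_metric: float = 9.0
    docked_metric: float = 6.0
    lateral_offset: float = 5.8
    barrier: float = 2.5
    undocked_bias: float = 4.0
    undocked_bias_sigma: float = 1.0
    ion_epsilon: float = 5.0
    ion_sigma: float = 0.4
    ion_cutoff_sigmas: float = 3.0
    bond_k: float = 30.0
    anchor_k: float = 50.0
    lateral_k: float = 6.0
    orient_k: float = 20.0
    wall_k: float = 25.0
    wall_offset: float = 0.2
    linker_k: float = 0.05
    scaffold_radius: float = 4.0
    jitter: float = 0.05
    mass: float = 1.0
    energy_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.undocked_metric > self.docked_metric):
            raise ValueError(
                "degenerate geometry: docked metric must be below undocked metric"
            )
        if self.docked_metric <= self.lateral_offset:
            raise ValueError(
                "docked metric must exceed the lateral offset of the catalytic sites"
            )
        if self.barrier <= 0 or self.energy_scale <= 0 or self.mass <= 0:
            raise ValueError("barrier, energy_scale and mass must be positive")

    @property
    def z_docked(self) -> float:
        return math.sqrt(self.docked_metric**2 - self.lateral_offset**2)

    @property
    def z_undocked(self) -> float:
        return math.sqrt(self.undocked_metric**2 - self.lateral_offset**2)

    @property
    def displacement(self) -> float:
        """Rigid-body travel of the mobile domain between the two poses."""
        return self.z_undocked - self.z_docked

    def with_displacement(self, displacement: float) -> "DockingGeometry":
        """Geometry whose undocked pose sits ``displacement`` above docked.

        The undocked→docked rigid translation equals the best-fit RMSD of the
        mobile beads between the poses, so this prepares a start pose at a
        prescribed initial RMSD for targeted-MD runs.
        """
        z_u = self.z_docked + displacement
        return replace(
            self, undocked_metric=math.hypot(self.lateral_offset, z_u)
        )

    @classmethod
    def physical_defaults(cls, temperature: float = 310.15) -> "DockingGeometry":
        """Å / kcal·mol⁻¹ / amu parameterization at the given temperature.

        The reduced-unit landscape is rescaled by kB·T so basin depths keep
        the same thermal meaning; bead masses and stiffnesses are softened to
        amino-acid-cluster scale so a 0.05 ps time step is stable.
        """
        kT = PHYSICAL.kB * temperature
        return cls(
            energy_scale=kT,
            mass=100.0,
            bond_k=13.0,
            anchor_k=13.0,
            lateral_k=6.5,
            orient_k=13.0,
            wall_k=13.0,
            undocked_bias_sigma=1.5,
        )


def _domain_offsets(w: float) -> dict[str, np.ndarray]:
    """Mobile-domain bead positions relative to the domain center."""
    return {
        "center": np.array([0.0, 0.0, 0.0]),
        "cat1": np.array([w, 0.0, 0.0]),
        "cat2": np.array([-w, 0.0, 0.0]),
        "fretA": np.array([0.0, 0.0, 1.5]),
        "b1": np.array([0.0, 1.5, 0.75]),
        "b2": np.array([0.0, -1.5, 0.75]),
    }


def make_domain_docking_model(
    geometry: DockingGeometry | None = None,
    ion_present: bool = True,
    seed: int = 0,
    units: UnitSystem = REDUCED,
) -> ParticleSystem:
    """Construct the docking fixture.

    Deterministic given ``(geometry, seed)``; the seed only jitters the
    decorative scaffold beads.  The returned system carries poses
    ``"undocked"`` and ``"docked"`` with the domain rigidly translated along
    the docking axis, site labels ``scissile``/``cat1``/``cat2``/``fretA``/
    ``fretB``/``fretC`` (plus ``ion`` when present), and groups
    ``scaffold``/``mobile_domain`` (plus ``ion``).
    """
    g = geometry if geometry is not None else DockingGeometry()
    es = g.energy_scale
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x0D0C)))

    w = g.lateral_offset
    z_d, z_u = g.z_docked, g.z_undocked
    r = g.scaffold_radius

    # Scaffold: scissile site, four base beads (jittered), two reporter posts.
    scaffold_home = [
        np.array([0.0, 0.0, 0.0]),  # 0 scissile
        np.array([r, 0.0, -1.0]),  # 1
        np.array([0.0, r, -1.0]),  # 2
        np.array([-r, 0.0, -1.0]),  # 3
        np.array([0.0, -r, -1.0]),  # 4
        np.array([0.0, 3.0, 5.0]),  # 5 fretB
        np.array([0.0, -3.0, 0.5]),  # 6 fretC
    ]
    for i in (1, 2, 3, 4):
        scaffold_home[i] = scaffold_home[i] + rng.normal(0.0, g.jitter, size=3)

    offsets = _domain_offsets(w)
    domain_order = ["center", "cat1", "cat2", "fretA", "b1", "b2"]
    n_scaffold = len(scaffold_home)
    domain_idx = {name: n_scaffold + k for k, name in enumerate(domain_order)}

    def pose(z_center: float) -> np.ndarray:
        dom = [np.array([0.0, 0.0, z_center]) + offsets[name] for name in domain_order]
        rows = scaffold_home + dom
        if ion_present:
            rows = rows + [ion_pos]
        return np.array(rows)

    ion_pos = np.array([0.0, 0.0, 2.0 * z_d / 3.0])  # centroid of cat1/cat2/scissile, docked

    terms: list = []
    # Scaffold pinning.
    for i, home in enumerate(scaffold_home):
        terms.append(Anchor(i=i, k=es * g.anchor_k, ref=tuple(home)))
    # Rigid-ish mobile domain: complete bond graph at docked-pose rest lengths.
    dom_positions = {n: offsets[n] for n in domain_order}
    for a in range(len(domain_order)):
        for b in range(a + 1, len(domain_order)):
            na, nb = domain_order[a], domain_order[b]
            r0 = float(np.linalg.norm(dom_positions[na] - dom_positions[nb]))
            terms.append(
                HarmonicBond(i=domain_idx[na], j=domain_idx[nb], k=es * g.bond_k, r0=r0)
            )
    # Docking coordinate: double well on the domain-center z.
    b_half = 0.5 * (z_u - z_d)
    terms.append(
        AxisDoubleWell(
            i=domain_idx["center"],
            axis=2,
            x1=z_u,
            x2=z_d,
            a=es * g.barrier / b_half**4,
            deepen_at=z_u,
            deepen_depth=es * g.undocked_bias,
            deepen_sigma=g.undocked_bias_sigma,
        )
    )
    # Lateral confinement of the domain center, and orientation tethers on
    # the apex bead (suppress rigid-body tilt; spin about the docking axis
    # stays free and is metric-invariant by symmetry).
    for axis in (0, 1):
        terms.append(
            AxisHarmonic(i=domain_idx["center"], axis=axis, k=es * g.lateral_k, center=0.0)
        )
        terms.append(
            AxisHarmonic(i=domain_idx["fretA"], axis=axis, k=es * g.orient_k, center=0.0)
        )
    # Steric contact walls just below the designed docked contact distance:
    # the catalytic sites cannot sink appreciably closer to the scissile
    # site, so the progress metric has a geometric floor near the docked
    # value (the docked pose itself sits clear of the wall).
    for cat in ("cat1", "cat2"):
        terms.append(
            PairRepulsion(
                i=0,
                j=domain_idx[cat],
                k=es * g.wall_k,
                r_wall=g.docked_metric - g.wall_offset,
            )
        )
    # Two flexible linkers tethering the domain to the scaffold.
    z_mid = 0.5 * (z_u + z_d)
    for dom_name, sc_idx in (("b1", 2), ("b2", 4)):
        p_dom = np.array([0.0, 0.0, z_mid]) + offsets[dom_name]
        r0 = float(np.linalg.norm(p_dom - scaffold_home[sc_idx]))
        terms.append(
            HarmonicBond(i=domain_idx[dom_name], j=sc_idx, k=es * g.linker_k, r0=r0)
        )

    site_labels = {
        "scissile": 0,
        "fretB": 5,
        "fretC": 6,
        "center": domain_idx["center"],
        "cat1": domain_idx["cat1"],
        "cat2": domain_idx["cat2"],
        "fretA": domain_idx["fretA"],
    }
    groups = {
        "scaffold": np.arange(n_scaffold),
        "mobile_domain": np.arange(n_scaffold, n_scaffold + len(domain_order)),
    }
    n = n_scaffold + len(domain_order)

    if ion_present:
        ion_idx = n
        n += 1
        site_labels["ion"] = ion_idx
        groups["ion"] = np.array([ion_idx])
        terms.append(Anchor(i=ion_idx, k=es * g.anchor_k, ref=tuple(ion_pos)))
        # Bridging attractions, minima exactly at the docked-pose distances.
        docked = {
            "cat1": np.array([w, 0.0, z_d]),
            "cat2": np.array([-w, 0.0, z_d]),
            "scissile": np.array([0.0, 0.0, 0.0]),
        }
        for label, p in docked.items():
            r0 = float(np.linalg.norm(p - ion_pos))
            terms.append(
                PairWell(
                    i=site_labels[label],
                    j=ion_idx,
                    epsilon=es * g.ion_epsilon,
                    r0=r0,
                    sigma=g.ion_sigma,
                    cutoff=r0 + g.ion_cutoff_sigmas * g.ion_sigma,
                )
            )

    system = ParticleSystem(
        masses=np.full(n, g.mass),
        terms=tuple(terms),
        site_labels=site_labels,
        groups=groups,
        units=units,
        poses={"undocked": pose(z_u), "docked": pose(z_d)},
        name="domain_docking",
    )
    return system


def make_tmd_docking_setup(
    initial_rmsd: float = 10.0,
    duration: float = 100_000.0,
    per_atom_spring: float = 0.25,
    restraint_k: float = 0.1,
    temperature: float = 310.15,
    seed: int = 0,
):
    """Physical-unit targeted-MD protocol on the docking fixture.

    Prepares an undocked start pose whose mass-weighted best-fit RMSD from
    the docked target equals ``initial_rmsd`` (Å) over the mobile domain,
    and steering parameters with the standard per-targeted-atom spring
    constant (0.25 kcal/mol/Å²) and a linear schedule driving the reference
    RMSD from ``initial_rmsd`` to zero over ``duration`` ps — i.e. a
    decrease rate of initial_rmsd/duration·1000 Å/ns (0.1 Å/ns at the
    defaults).  Non-targeted scaffold beads are weakly restrained
    (``restraint_k`` kcal/mol/Å²) against solute drift.

    Returns ``(system, TmdParams)``; run with ``TmdBias`` and an engine in
    physical units at ``temperature``.
    """
    from .biasing import PositionalRestraintParams, TmdParams, TmdSchedule

    g = DockingGeometry.physical_defaults(temperature).with_displacement(initial_rmsd)
    system = make_domain_docking_model(g, ion_present=False, seed=seed, units=PHYSICAL)
    targeted = system.group("mobile_domain")
    scaffold = system.group("scaffold")
    params = TmdParams(
        k=per_atom_spring * len(targeted),
        targeted_indices=targeted,
        target_coords=system.poses["docked"],
        schedule=TmdSchedule(0.0, duration, initial_rmsd, 0.0),
        weights="mass",
        fit_indices=scaffold,
        restraint=PositionalRestraintParams(
            indices=scaffold,
            k=restraint_k,
            reference=system.poses["undocked"][scaffold],
        ),
    )
    return system, params
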