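"""Langevin / velocity-Verlet dynamics with pluggable bias forces.

Forces are evaluated through a per-system compiled cache that groups terms of
the same type into index arrays, so one step costs a handful of vectorized
numpy operations regardless of term count.  The integrator is the BAOAB
splitting of Langevin dynamics; with zero friction and zero temperature it
reduces exactly to velocity Verlet.

Biases (accelerated-MD boost, targeted-MD steering, positional restraints —
see :mod:`stepmd.biasing`) hook into every step through a small protocol:
``bias.apply(t, coords, energy, forces, channels)`` mutates the force array
in place and returns a dict of named bias energies that is stored per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .system import (
    Anchor,
    AxisDoubleWell,
    AxisHarmonic,
    HarmonicBond,
    Landscape1D,
    MuellerBrown2D,
    PairRepulsion,
    PairWell,
    ParticleSystem,
)
from .trajectory import Frame, Trajectory

__all__ = [
    "EngineParams",
    "EngineState",
    "EngineError",
    "ChannelBreakdown",
    "compute_forces",
    "step_langevin",
    "run_md",
    "maxwell_boltzmann_velocities",
    "derive_rng",
]


class EngineError(RuntimeError):
    """Raised when integration fails (non-finite or exploding energies)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message if step is None else f"step {step}: {message}")
        self.step = step


@dataclass(frozen=True)
class EngineParams:
    """Integrator settings.

    dt : time step (reduced time or ps)
    temperature : thermostat target (reduced kT or Kelvin)
    friction : Langevin collision rate (1/time); 0 disables the O-step
    seed : RNG seed for thermostat noise and initial velocities
    n_steps : number of integration steps
    save_interval : store a frame every this many steps (the saved frames are
        a strided subset of the dense run)
    energy_bound : abort with EngineError if the potential exceeds this
    save_velocities : keep velocities in saved frames
    """

    dt: float
    temperature: float = 1.0
    friction: float = 1.0
    seed: int = 0
    n_steps: int = 1000
    save_interval: int = 10
    energy_bound: float = 1e8
    save_velocities: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0 or self.temperature < 0:
            raise ValueError("friction and temperature must be non-negative")
        if self.n_steps < 0 or self.save_interval < 1:
            raise ValueError("n_steps >= 0 and save_interval >= 1 required")


@dataclass
class EngineState:
    """Instantaneous dynamical state."""

    coords: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    potential_energy: float
    step: int = 0
    time: float = 0.0
    bias_values: dict[str, float] = field(default_factory=dict)


class Bias(Protocol):
    def apply(
        self,
        t: float,
        coords: np.ndarray,
        energy: float,
        forces: np.ndarray,
        channels: "ChannelBreakdown",
    ) -> dict[str, float]: ...


@dataclass
class ChannelBreakdown:
    """Per-channel energy/force split used by dual-boost accelerated MD.

    ``internal`` covers the designated internal-coordinate terms (the
    double-well terms standing in for dihedrals); ``total`` is the full
    potential.
    """

    internal_energy: float
    internal_forces: np.ndarray
    total_energy: float
    total_forces: np.ndarray


class _Compiled:
    """Vectorized term arrays for one ParticleSystem."""

    def __init__(self, system: ParticleSystem):
        bonds = [t for t in system.terms if isinstance(t, HarmonicBond)]
        self.bond_i = np.array([t.i for t in bonds], dtype=int)
        self.bond_j = np.array([t.j for t in bonds], dtype=int)
        self.bond_k = np.array([t.k for t in bonds])
        self.bond_r0 = np.array([t.r0 for t in bonds])

        pairs = [t for t in system.terms if isinstance(t, PairWell)]
        self.pair_i = np.array([t.i for t in pairs], dtype=int)
        self.pair_j = np.array([t.j for t in pairs], dtype=int)
        self.pair_eps = np.array([t.epsilon for t in pairs])
        self.pair_r0 = np.array([t.r0 for t in pairs])
        self.pair_sig = np.array([t.sigma for t in pairs])
        self.pair_cut = np.array([t.cutoff for t in pairs])
        with np.errstate(over="ignore"):
            self.pair_shift = np.exp(
                -((self.pair_cut - self.pair_r0) ** 2) / (2.0 * self.pair_sig**2)
            )

        reps = [t for t in system.terms if isinstance(t, PairRepulsion)]
        self.rep_i = np.array([t.i for t in reps], dtype=int)
        self.rep_j = np.array([t.j for t in reps], dtype=int)
        self.rep_k = np.array([t.k for t in reps])
        self.rep_rw = np.array([t.r_wall for t in reps])

        anchors = [t for t in system.terms if isinstance(t, Anchor)]
        self.anchor_i = np.array([t.i for t in anchors], dtype=int)
        self.anchor_k = np.array([t.k for t in anchors])[:, None]
        self.anchor_ref = np.array([t.ref for t in anchors]).reshape(-1, 3)

        axh = [t for t in system.terms if isinstance(t, AxisHarmonic)]
        self.axh_i = np.array([t.i for t in axh], dtype=int)
        self.axh_ax = np.array([t.axis for t in axh], dtype=int)
        self.axh_k = np.array([t.k for t in axh])
        self.axh_c = np.array([t.center for t in axh])

        adw = [t for t in system.terms if isinstance(t, AxisDoubleWell)]
        self.adw_i = np.array([t.i for t in adw], dtype=int)
        self.adw_ax = np.array([t.axis for t in adw], dtype=int)
        self.adw_x1 = np.array([t.x1 for t in adw])
        self.adw_x2 = np.array([t.x2 for t in adw])
        self.adw_a = np.array([t.a for t in adw])
        self.adw_dd = np.array([t.deepen_depth for t in adw])
        self.adw_dp = np.array([t.deepen_at for t in adw])
        self.adw_ds = np.array([t.deepen_sigma for t in adw])

        self.landscapes = [
            t for t in system.terms if isinstance(t, (Landscape1D, MuellerBrown2D))
        ]
        self.n = system.n_particles

        # Flattened scatter indices for a single-bincount force accumulation:
        # every pairwise term contributes at rows i (+f) and j (−f), tether
        # and axis terms at single slots.
        def flat3(idx):
            return (3 * idx[:, None] + np.arange(3)[None, :]).ravel()

        self.scatter_flat = np.concatenate(
            [
                flat3(self.bond_i), flat3(self.bond_j),
                flat3(self.pair_i), flat3(self.pair_j),
                flat3(self.rep_i), flat3(self.rep_j),
                flat3(self.anchor_i),
                3 * self.axh_i + self.axh_ax,
                3 * self.adw_i + self.adw_ax,
            ]
        ).astype(np.intp)
        self.adw_flat = 3 * self.adw_i + self.adw_ax
        self.flat_n = 3 * self.n


def _compiled(system: ParticleSystem) -> _Compiled:
    cache = getattr(system, "_compiled_cache", None)
    if cache is None or cache.n != system.n_particles:
        cache = _Compiled(system)
        system._compiled_cache = cache  # type: ignore[attr-defined]
    return cache


def compute_forces(
    system: ParticleSystem, coords: np.ndarray, channels: bool = False
) -> tuple[float, np.ndarray] | tuple[float, np.ndarray, ChannelBreakdown]:
    """Potential energy and forces (−∇V) summed over all terms.

    With ``channels=True`` additionally returns the internal-channel split
    needed by dual-boost accelerated MD.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_particles, 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match system ({system.n_particles}, 3)"
        )
    if not np.all(np.isfinite(coords)):
        raise EngineError("non-finite coordinates")
    c = _compiled(system)
    energy = 0.0
    e_int = 0.0
    f_int = np.zeros_like(coords) if channels else None
    flat = coords.ravel()
    values = []  # force contributions, ordered to match c.scatter_flat

    if c.bond_i.size:
        d = coords[c.bond_i] - coords[c.bond_j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        dr = r - c.bond_r0
        energy += 0.5 * np.dot(c.bond_k, dr * dr)
        fvec = (-c.bond_k * dr / np.maximum(r, 1e-12))[:, None] * d
        values += [fvec.ravel(), -fvec.ravel()]

    if c.pair_i.size:
        d = coords[c.pair_i] - coords[c.pair_j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        inside = r < c.pair_cut
        g = np.exp(-((r - c.pair_r0) ** 2) / (2.0 * c.pair_sig**2))
        energy += np.sum(np.where(inside, -c.pair_eps * (g - c.pair_shift), 0.0))
        # dV/dr = ε·g·(r−r0)/σ²  → force along d is −dV/dr · d/r
        dvdr = np.where(inside, c.pair_eps * g * (r - c.pair_r0) / c.pair_sig**2, 0.0)
        fvec = (-dvdr / np.maximum(r, 1e-12))[:, None] * d
        values += [fvec.ravel(), -fvec.ravel()]

    if c.rep_i.size:
        d = coords[c.rep_i] - coords[c.rep_j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        pen = np.minimum(r - c.rep_rw, 0.0)
        energy += 0.5 * np.dot(c.rep_k, pen * pen)
        fvec = (-c.rep_k * pen / np.maximum(r, 1e-12))[:, None] * d
        values += [fvec.ravel(), -fvec.ravel()]

    if c.anchor_i.size:
        d = coords[c.anchor_i] - c.anchor_ref
        energy += 0.5 * np.sum(c.anchor_k * d**2)
        values.append((-c.anchor_k * d).ravel())

    if c.axh_i.size:
        u = flat[3 * c.axh_i + c.axh_ax] - c.axh_c
        energy += 0.5 * np.dot(c.axh_k, u * u)
        values.append(-c.axh_k * u)

    if c.adw_i.size:
        u = flat[c.adw_flat]
        d1 = u - c.adw_x1
        d2 = u - c.adw_x2
        g = np.exp(-((u - c.adw_dp) ** 2) / (2.0 * c.adw_ds**2))
        e_term = np.sum(c.adw_a * d1**2 * d2**2 - c.adw_dd * g)
        dv = 2.0 * c.adw_a * d1 * d2 * (d1 + d2) + c.adw_dd * g * (
            u - c.adw_dp
        ) / c.adw_ds**2
        energy += e_term
        e_int += e_term
        values.append(-dv)
        if channels:
            np.add.at(f_int, (c.adw_i, c.adw_ax), -dv)

    if values:
        forces = np.bincount(
            c.scatter_flat, weights=np.concatenate(values), minlength=c.flat_n
        ).reshape(coords.shape)
    else:
        forces = np.zeros_like(coords)

    for t in c.landscapes:
        if isinstance(t, Landscape1D):
            x = coords[t.i, 0]
            e = t.energy(x)
            gx = t.gradient(x)
            energy += e
            forces[t.i, 0] -= gx
            if t.channel == "internal":
                e_int += e
                if channels:
                    f_int[t.i, 0] -= gx
        else:
            x, y = coords[t.i, 0], coords[t.i, 1]
            e = t.energy(x, y)
            gx, gy = t.gradient(x, y)
            energy += e
            forces[t.i, 0] -= gx
            forces[t.i, 1] -= gy

    energy = float(energy)
    if channels:
        return energy, forces, ChannelBreakdown(float(e_int), f_int, energy, forces)
    return energy, forces


def maxwell_boltzmann_velocities(
    system: ParticleSystem, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw velocities from the Maxwell–Boltzmann distribution at T."""
    kT = system.units.thermal_energy(temperature)
    sigma = np.sqrt(system.units.acc_factor * kT / system.masses)[:, None]
    return rng.normal(0.0, 1.0, size=(system.n_particles, 3)) * sigma


def derive_rng(master_seed: int, *stream_ids: int) -> np.random.Generator:
    """Reproducible per-replica RNG stream from a campaign master seed.

    Uses numpy's SeedSequence entropy-pooling over (master, ids...) — a
    collision-resistant hash, so replica/cycle streams are independent.
    """
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed),) + tuple(int(i) for i in stream_ids))
    )


def _biased_forces(
    system: ParticleSystem,
    coords: np.ndarray,
    t: float,
    biases: Sequence[Bias],
) -> tuple[float, np.ndarray, dict[str, float]]:
    if biases:
        energy, forces, ch = compute_forces(system, coords, channels=True)
        record: dict[str, float] = {}
        for bias in biases:
            record.update(bias.apply(t, coords, energy, forces, ch))
        return energy, forces, record
    energy, forces = compute_forces(system, coords)
    return energy, forces, {}


def step_langevin(
    state: EngineState,
    system: ParticleSystem,
    params: EngineParams,
    biases: Sequence[Bias] = (),
    rng: np.random.Generator | None = None,
) -> EngineState:
    """One BAOAB Langevin update (in place on copies; returns new state).

    With friction = 0 the O-step is the identity and the scheme reduces to
    velocity Verlet; forces include bias contributions.
    """
    if rng is None:
        rng = derive_rng(params.seed, state.step)
    dt = params.dt
    conv = system.units.acc_factor
    inv_m = (conv / system.masses)[:, None]

    v = state.velocities + 0.5 * dt * state.forces * inv_m
    x = state.coords + 0.5 * dt * v
    if params.friction > 0.0:
        c1 = math.exp(-params.friction * dt)
        kT = system.units.thermal_energy(params.temperature)
        sigma = np.sqrt((1.0 - c1 * c1) * conv * kT / system.masses)[:, None]
        v = c1 * v + sigma * rng.normal(0.0, 1.0, size=v.shape)
    x = x + 0.5 * dt * v
    t_new = state.time + dt
    energy, forces, record = _biased_forces(system, x, t_new, biases)
    if not np.isfinite(energy) or energy > params.energy_bound:
        raise EngineError(
            f"energy {energy:.3g} exceeds bound {params.energy_bound:.3g} "
            "(time step too large?)",
            step=state.step + 1,
        )
    v = v + 0.5 * dt * forces * inv_m
    return EngineState(
        coords=x,
        velocities=v,
        forces=forces,
        potential_energy=energy,
        step=state.step + 1,
        time=t_new,
        bias_values=record,
    )


def run_md(
    system: ParticleSystem,
    params: EngineParams,
    biases: Sequence[Bias] = (),
    initial: Frame | None = None,
) -> Trajectory:
    """Integrate ``params.n_steps`` steps, saving every ``save_interval``.

    The initial frame is always stored.  If the initial frame carries no
    velocities they are drawn from the Maxwell–Boltzmann distribution at the
    target temperature using ``params.seed``.  Identical parameters and seed
    reproduce the trajectory bit for bit.
    """
    if initial is None:
        pose = system.poses.get("undocked")
        if pose is None:
            raise ValueError("no initial frame given and system has no 'undocked' pose")
        initial = Frame(time=0.0, coords=pose.copy())
    if initial.coords.shape != (system.n_particles, 3):
        raise ValueError("initial frame does not match system size")
    rng = derive_rng(params.seed)
    velocities = (
        initial.velocities.copy()
        if initial.velocities is not None
        else maxwell_boltzmann_velocities(system, params.temperature, rng)
    )
    energy, forces, record = _biased_forces(system, initial.coords, initial.time, biases)
    state = EngineState(
        coords=initial.coords.copy(),
        velocities=velocities,
        forces=forces,
        potential_energy=energy,
        step=0,
        time=initial.time,
        bias_values=record,
    )

    def snapshot(s: EngineState) -> Frame:
        return Frame(
            time=s.time,
            coords=s.coords.copy(),
            velocities=s.velocities.copy() if params.save_velocities else None,
            potential_energy=s.potential_energy,
            bias_values=dict(s.bias_values),
        )

    frames = [snapshot(state)]
    try:
        for _ in range(params.n_steps):
            state = step_langevin(state, system, params, biases, rng)
            if state.step % params.save_interval == 0:
                frames.append(snapshot(state))
    except EngineError:
        raise
    return Trajectory(
        frames=frames,
        system_ref=system.name,
        metadata={
            "seed": params.seed,
            "dt": params.dt,
            "temperature": params.temperature,
            "friction": params.friction,
            "n_steps": params.n_steps,
            "save_interval": params.save_interval,
            "biases": [type(b).__name__ for b in biases],
        },
    )
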