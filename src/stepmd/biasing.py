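"""Bias potentials: accelerated-MD boost and targeted-MD steering.

Accelerated MD (aMD)
--------------------
A non-negative boost raises basins lying below a threshold energy E:

    ΔV(r) = 0                       if V(r) ≥ E
          = (E−V)² / (α + (E−V))    if V(r) <  E

The acceleration factor α sets the depth and residual roughness of the
modified basins: the boosted potential V+ΔV = E − α(E−V)/(α+E−V) is bounded
in (E−α, E], monotone in V, and the biased force is the unbiased force times
α²/(α+E−V)² ∈ (0, 1].  Two boost modes are supported: ``dihedral_only``
(boosting the designated internal-coordinate channel) and ``dual`` (an extra
boost on the full potential).  Reweighting with exp(ΔV/kT) (or its
second-order cumulant approximation) recovers unbiased free-energy profiles.

Targeted MD (tMD)
-----------------
A harmonic penalty on the gap between the instantaneous best-fit RMSD to a
target structure and a reference RMSD*(t) that decreases linearly over the
schedule:

    U_tMD = ½ (k/N) [RMSD(t) − RMSD*(t)]²

with the spring constant k scaled down by the number N of targeted atoms.
Weights may be uniform or mass-weighted; non-targeted low-mobility atoms can
be held by a weak positional restraint to prevent solute drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .engine import ChannelBreakdown
from .system import ParticleSystem
from .trajectory import Frame, Trajectory

__all__ = [
    "AmdParams",
    "AmdBias",
    "CmdStats",
    "AmdRecipeCoeffs",
    "amd_boost",
    "amd_force_factor",
    "estimate_amd_params",
    "FreeEnergyProfile",
    "reweight_profile",
    "profile_from_trajectory",
    "kabsch_superpose",
    "TmdSchedule",
    "PositionalRestraintParams",
    "TmdParams",
    "TmdBias",
    "RestraintBias",
    "tmd_bias",
    "positional_restraint",
]


# --------------------------------------------------------------------------
# aMD boost
# --------------------------------------------------------------------------


def amd_boost(V: float, E: float, alpha: float) -> float:
    """Boost energy ΔV for instantaneous channel energy V."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if V >= E:
        return 0.0
    gap = E - V
    return gap * gap / (alpha + gap)


def amd_force_factor(V: float, E: float, alpha: float) -> float:
    """Multiplier d(V+ΔV)/dV on the channel's unbiased force, in (0, 1]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if V >= E:
        return 1.0
    ratio = alpha / (alpha + (E - V))
    return ratio * ratio


@dataclass(frozen=True)
class AmdParams:
    """Boost thresholds/acceleration factors per channel.

    ``internal`` is the dihedral-analog channel (the fixture's designated
    double-well terms); ``total`` is the full potential, used only in
    ``dual`` mode.
    """

    mode: Literal["dihedral_only", "dual"]
    E_internal: float
    alpha_internal: float
    E_total: float | None = None
    alpha_total: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("dihedral_only", "dual"):
            raise ValueError(f"unknown aMD mode {self.mode!r}")
        if self.alpha_internal <= 0:
            raise ValueError("alpha_internal must be positive")
        if self.mode == "dual":
            if self.E_total is None or self.alpha_total is None:
                raise ValueError("dual mode requires E_total and alpha_total")
            if self.alpha_total <= 0:
                raise ValueError("alpha_total must be positive")
        elif self.E_total is not None or self.alpha_total is not None:
            raise ValueError("dihedral_only mode takes a single channel")


@dataclass(frozen=True)
class CmdStats:
    """Channel-energy averages from a short conventional-MD run, plus the
    size measures the threshold/acceleration recipe scales with."""

    mean_internal_energy: float
    mean_total_energy: float
    internal_size: float
    total_size: float

    @classmethod
    def from_trajectory(cls, traj: Trajectory, system: ParticleSystem) -> "CmdStats":
        from .engine import compute_forces

        e_int, e_tot = [], []
        for f in traj:
            e, _, ch = compute_forces(system, f.coords, channels=True)
            e_int.append(ch.internal_energy)
            e_tot.append(e)
        n_internal = sum(1 for t in system.terms if getattr(t, "channel", "") == "internal")
        return cls(
            mean_internal_energy=float(np.mean(e_int)),
            mean_total_energy=float(np.mean(e_tot)),
            internal_size=float(n_internal),
            total_size=float(system.n_particles),
        )


@dataclass(frozen=True)
class AmdRecipeCoeffs:
    """Configurable coefficients of the E/α estimation recipe.

    E_channel = ⟨V_channel⟩ + cE·size, α_channel = cα·size.  The defaults
    follow the shape of the standard protein recipe (threshold offset and
    acceleration proportional to system size) rescaled to the toy systems'
    size measures: number of internal-coordinate terms for the internal
    channel, number of particles for the total channel.
    """

    e_internal: float = 3.5
    alpha_internal: float = 0.7
    e_total: float = 0.2
    alpha_total: float = 0.2


def estimate_amd_params(
    stats: CmdStats,
    mode: Literal["dihedral_only", "dual"] = "dual",
    coeffs: AmdRecipeCoeffs | None = None,
) -> AmdParams:
    """Boost parameters from conventional-MD channel statistics.

    Pure function of its inputs: E = ⟨V⟩ + cE·size and α = cα·size per
    channel.  Raises if any acceleration factor comes out non-positive
    (e.g. a zero-size system).
    """
    c = coeffs if coeffs is not None else AmdRecipeCoeffs()
    if not np.isfinite([stats.mean_internal_energy, stats.mean_total_energy]).all():
        raise ValueError("channel energy means must be finite")
    alpha_i = c.alpha_internal * stats.internal_size
    if alpha_i <= 0:
        raise ValueError("internal-channel alpha computed non-positive (zero size?)")
    E_i = stats.mean_internal_energy + c.e_internal * stats.internal_size
    if mode == "dihedral_only":
        return AmdParams(mode=mode, E_internal=E_i, alpha_internal=alpha_i)
    alpha_t = c.alpha_total * stats.total_size
    if alpha_t <= 0:
        raise ValueError("total-channel alpha computed non-positive (zero size?)")
    E_t = stats.mean_total_energy + c.e_total * stats.total_size
    return AmdParams(
        mode="dual",
        E_internal=E_i,
        alpha_internal=alpha_i,
        E_total=E_t,
        alpha_total=alpha_t,
    )


class AmdBias:
    """Engine bias applying the boost each step.

    The modified potential is V* = V + ΔV_int(V_int) [+ ΔV_tot(V)], so the
    biased force is f_tot·F + (f_int − 1)·F_int with the per-channel force
    factors; the per-frame record holds the boost split for reweighting.
    """

    def __init__(self, params: AmdParams):
        self.params = params

    def apply(
        self,
        t: float,
        coords: np.ndarray,
        energy: float,
        forces: np.ndarray,
        channels: ChannelBreakdown,
    ) -> dict[str, float]:
        p = self.params
        dv_int = amd_boost(channels.internal_energy, p.E_internal, p.alpha_internal)
        f_int = amd_force_factor(channels.internal_energy, p.E_internal, p.alpha_internal)
        record = {"amd_internal": dv_int}
        if p.mode == "dual":
            dv_tot = amd_boost(channels.total_energy, p.E_total, p.alpha_total)
            f_tot = amd_force_factor(channels.total_energy, p.E_total, p.alpha_total)
            forces *= f_tot
            record["amd_total"] = dv_tot
        forces += (f_int - 1.0) * channels.internal_forces
        return record


# --------------------------------------------------------------------------
# Reweighting
# --------------------------------------------------------------------------


@dataclass
class FreeEnergyProfile:
    """Free energy over observable bins; empty bins are NaN, min is zero."""

    edges: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def barrier(self, between: tuple[float, float]) -> float:
        """Highest free energy over the observable interval ``between``."""
        lo, hi = sorted(between)
        mask = (self.centers >= lo) & (self.centers <= hi)
        vals = self.free_energy[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no populated bins in the requested interval")
        return float(np.max(vals))


def reweight_profile(
    observable: np.ndarray,
    delta_v: np.ndarray,
    temperature: float,
    bins: int | np.ndarray = 50,
    estimator: Literal["exponential", "cumulant2"] = "exponential",
) -> FreeEnergyProfile:
    """Unbiased free-energy profile from boosted sampling.

    Each sample carries the total boost ΔV it experienced; exponential
    reweighting weights it by exp(ΔV/kT) (evaluated shift-stabilized), and
    F(bin) = −kT·ln Σ_bin weight, re-zeroed at the minimum.  The
    ``cumulant2`` estimator instead uses the second-order cumulant expansion
    F(bin) = −kT·ln n_bin − ⟨ΔV⟩_bin − Var(ΔV)_bin/(2kT), which trades bias
    for variance when the boost is large.  With ΔV ≡ const both reduce to
    −kT·ln(histogram).  Empty bins are reported as NaN, never zero.
    """
    obs = np.asarray(observable, dtype=float).ravel()
    dv = np.asarray(delta_v, dtype=float).ravel()
    if obs.shape != dv.shape:
        raise ValueError("observable and delta_v must have the same length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    edges = np.histogram_bin_edges(obs, bins=bins)
    idx = np.clip(np.digitize(obs, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    free = np.full(len(edges) - 1, np.nan)
    if estimator == "exponential":
        shift = dv.max() if dv.size else 0.0
        w = np.exp((dv - shift) / temperature)
        wsum = np.bincount(idx, weights=w, minlength=len(edges) - 1)
        pop = wsum > 0
        free[pop] = -temperature * np.log(wsum[pop])
    elif estimator == "cumulant2":
        pop = counts > 0
        mean = np.bincount(idx, weights=dv, minlength=len(edges) - 1)
        mean[pop] = mean[pop] / counts[pop]
        sq = np.bincount(idx, weights=dv**2, minlength=len(edges) - 1)
        var = np.zeros_like(mean)
        var[pop] = sq[pop] / counts[pop] - mean[pop] ** 2
        free[pop] = (
            -temperature * np.log(counts[pop])
            - mean[pop]
            - var[pop] / (2.0 * temperature)
        )
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if np.any(np.isfinite(free)):
        free -= np.nanmin(free)
    return FreeEnergyProfile(edges=edges, free_energy=free, counts=counts)


def profile_from_trajectory(
    traj: Trajectory,
    observable: Callable[[Frame], float],
    temperature: float,
    bins: int | np.ndarray = 50,
    estimator: Literal["exponential", "cumulant2"] = "exponential",
) -> FreeEnergyProfile:
    """Reweighted profile of a per-frame observable; ΔV read from the frames."""
    obs = np.array([observable(f) for f in traj])
    dv = traj.bias_series("amd")
    return reweight_profile(obs, dv, temperature, bins=bins, estimator=estimator)


# --------------------------------------------------------------------------
# Superposition and tMD
# --------------------------------------------------------------------------


def _superpose_transform(
    X: np.ndarray, Y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t with Y @ R.T + t best matching X."""
    W = w.sum()
    wcol = w[:, None]
    xc = (wcol * X).sum(axis=0) / W
    yc = (wcol * Y).sum(axis=0) / W
    Xc = X - xc
    Yc = Y - yc
    H = Yc.T @ (wcol * Xc)
    U, S, Vt = np.linalg.svd(H)
    scale = max(float(S[0]), float(np.sqrt((wcol * Xc**2).sum())), 1e-300)
    if S[1] <= 1e-9 * scale:
        raise ValueError("degenerate (collinear) point set: rotation ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = (Vt.T * np.array([1.0, 1.0, d])) @ U.T
    t = xc - yc @ R.T
    return R, t


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of Y onto X.

    Returns ``(R, t, rmsd)`` with det(R) = +1 such that ``Y @ R.T + t``
    minimizes the weighted RMSD to X.  Degenerate (collinear or < 3 point)
    inputs raise ValueError; reflections are never returned.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be matching (n, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with positive sum")
    R, t = _superpose_transform(X, Y, w)
    diff = X - (Y @ R.T + t)
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / w.sum()))
    return R, t, rmsd


@dataclass(frozen=True)
class TmdSchedule:
    """Linear reference-RMSD schedule, clamped outside [t_start, t_end]."""

    t_start: float
    t_end: float
    rmsd_initial: float
    rmsd_final: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not (self.rmsd_initial >= self.rmsd_final >= 0):
            raise ValueError("need rmsd_initial >= rmsd_final >= 0")

    def target(self, t: float) -> float:
        if t <= self.t_start:
            return self.rmsd_initial
        if t >= self.t_end:
            return self.rmsd_final
        frac = (t - self.t_start) / (self.t_end - self.t_start)
        return self.rmsd_initial + frac * (self.rmsd_final - self.rmsd_initial)

    @property
    def rate(self) -> float:
        """Scheduled RMSD decrease rate (length per time, positive)."""
        return (self.rmsd_initial - self.rmsd_final) / (self.t_end - self.t_start)


@dataclass(frozen=True)
class PositionalRestraintParams:
    """Weak harmonic tethers on selected atoms: Σ ½·k·|x_i − ref_i|²."""

    indices: np.ndarray
    k: float
    reference: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "reference", np.asarray(self.reference, dtype=float))
        if self.reference.shape != (len(self.indices), 3):
            raise ValueError("reference must be (n_restrained, 3)")
        if self.k < 0:
            raise ValueError("restraint force constant must be non-negative")


@dataclass(frozen=True)
class TmdParams:
    """Targeted-MD settings.

    ``k`` is the total spring constant of U = ½(k/N)(RMSD−RMSD*)²; the
    effective per-atom constant is k/N.  ``target_coords`` is a full-system
    coordinate set; RMSD is measured over ``targeted_indices`` after
    superposing the target onto the current frame over ``fit_indices``
    (default: the targeted atoms themselves).  ``weights`` selects uniform or
    mass weighting of both the fit and the RMSD.
    """

    k: float
    targeted_indices: np.ndarray
    target_coords: np.ndarray
    schedule: TmdSchedule
    weights: Literal["uniform", "mass"] = "uniform"
    fit_indices: np.ndarray | None = None
    restraint: PositionalRestraintParams | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "targeted_indices", np.asarray(self.targeted_indices, dtype=int))
        object.__setattr__(self, "target_coords", np.asarray(self.target_coords, dtype=float))
        if self.fit_indices is not None:
            object.__setattr__(self, "fit_indices", np.asarray(self.fit_indices, dtype=int))
        if self.k <= 0:
            raise ValueError("spring constant k must be positive")
        if len(self.targeted_indices) < 3:
            raise ValueError("need at least 3 targeted atoms")
        if self.target_coords.ndim != 2 or self.target_coords.shape[1] != 3:
            raise ValueError("target_coords must be (n_particles, 3)")
        if self.restraint is not None:
            overlap = set(self.restraint.indices) & set(self.targeted_indices.tolist())
            if overlap:
                warnings.warn(
                    f"restraint overlaps targeted atoms {sorted(overlap)}",
                    stacklevel=2,
                )

    @property
    def n_targeted(self) -> int:
        return len(self.targeted_indices)


def _tmd_weights(params: TmdParams, masses: np.ndarray, indices: np.ndarray) -> np.ndarray:
    if params.weights == "mass":
        return masses[indices].astype(float)
    return np.ones(len(indices))


def tmd_bias(
    coords: np.ndarray,
    t: float,
    params: TmdParams,
    masses: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Steering energy and forces at time ``t``.

    Returns ``(U, forces, rmsd)`` with forces only on the targeted atoms.
    The RMSD gradient keeps the explicit coordinate dependence after optimal
    superposition (the rotation-gradient terms vanish at the optimum):
    ∂RMSD/∂x_i = w_i·(x_i − y'_i)/(W·RMSD), so the force vanishes when
    RMSD = RMSD*.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != params.target_coords.shape:
        raise ValueError("coords do not match target_coords shape")
    if masses is None:
        masses = np.ones(coords.shape[0])
    tgt = params.targeted_indices
    fit = params.fit_indices if params.fit_indices is not None else tgt
    w_fit = _tmd_weights(params, masses, fit)
    R, tr = _superpose_transform(coords[fit], params.target_coords[fit], w_fit)
    aligned_target = params.target_coords[tgt] @ R.T + tr

    w = _tmd_weights(params, masses, tgt)
    W = w.sum()
    diff = coords[tgt] - aligned_target
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / W))
    rmsd_ref = params.schedule.target(t)
    k_eff = params.k / params.n_targeted
    gap = rmsd - rmsd_ref
    U = 0.5 * k_eff * gap * gap
    forces = np.zeros_like(coords)
    if rmsd > 1e-12:
        grad = (w[:, None] * diff) / (W * rmsd)
        forces[tgt] = -k_eff * gap * grad
    return U, forces, rmsd


def positional_restraint(
    coords: np.ndarray, params: PositionalRestraintParams
) -> tuple[float, np.ndarray]:
    """Harmonic tether energy and analytic forces (full-system force array)."""
    coords = np.asarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    d = coords[params.indices] - params.reference
    energy = 0.5 * params.k * float((d**2).sum())
    forces[params.indices] = -params.k * d
    return energy, forces


class TmdBias:
    """Engine bias applying targeted-MD steering (plus optional restraint).

    Records the instantaneous best-fit RMSD in ``rmsd_trace`` (time, RMSD,
    RMSD*) every ``trace_interval`` force evaluations for schedule-tracking
    analysis.
    """

    def __init__(
        self, params: TmdParams, system: ParticleSystem, trace_interval: int = 1
    ):
        self.params = params
        self.masses = system.masses
        self.trace_interval = max(int(trace_interval), 1)
        self._calls = 0
        self.rmsd_trace: list[tuple[float, float, float]] = []

    def apply(
        self,
        t: float,
        coords: np.ndarray,
        energy: float,
        forces: np.ndarray,
        channels: ChannelBreakdown,
    ) -> dict[str, float]:
        U, f, rmsd = tmd_bias(coords, t, self.params, self.masses)
        forces += f
        if self._calls % self.trace_interval == 0:
            self.rmsd_trace.append((t, rmsd, self.params.schedule.target(t)))
        self._calls += 1
        record = {"tmd": U}
        if self.params.restraint is not None:
            er, fr = positional_restraint(coords, self.params.restraint)
            forces += fr
            record["restraint"] = er
        return record


class RestraintBias:
    """Standalone positional-restraint bias."""

    def __init__(self, params: PositionalRestraintParams):
        self.params = params

    def apply(
        self,
        t: float,
        coords: np.ndarray,
        energy: float,
        forces: np.ndarray,
        channels: ChannelBreakdown,
    ) -> dict[str, float]:
        er, fr = positional_restraint(coords, self.params)
        forces += fr
        return {"restraint": er}
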