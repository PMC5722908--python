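"""Trajectory analysis: fit-excluded PCA, distances, RMSD, clustering,
coordination geometry and a pairwise interaction decomposition.

The PCA protocol follows the domain-motion convention: every frame is first
rigid-body fitted to a reference over a *fit selection* (the scaffold,
excluding the mobile domain), then the coordinate covariance matrix is
computed over the *analysis selection* (the mobile domain) and
eigendecomposed.  Projections of trajectories onto the leading modes give
the low-dimensional conformational-space maps used to compare sampling
methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .biasing import kabsch_superpose
from .system import PairWell, ParticleSystem
from .trajectory import Frame, Trajectory

__all__ = [
    "fit_superpose_series",
    "PcaResult",
    "pca_modes",
    "project_trajectory",
    "distance_pairs_series",
    "groupwise_rmsd",
    "ClusterResult",
    "cluster_representative",
    "CoordinationReport",
    "coordination_geometry",
    "interaction_decomposition",
]


def fit_superpose_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: np.ndarray,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Rigid-fit every frame to ``reference`` over ``fit_selection`` only.

    The optimal transform is computed from the fit selection and applied to
    the whole frame, so the mobile selection is carried along untouched by
    any additional fitting.  Idempotent on an already-aligned trajectory.
    """
    fit_selection = np.asarray(fit_selection, dtype=int)
    reference = np.asarray(reference, dtype=float)
    frames = []
    for f in traj:
        R, t, _ = kabsch_superpose(
            reference[fit_selection], f.coords[fit_selection], weights
        )
        frames.append(
            Frame(
                time=f.time,
                coords=f.coords @ R.T + t,
                potential_energy=f.potential_energy,
                bias_values=dict(f.bias_values),
            )
        )
    return Trajectory(
        frames=frames,
        system_ref=traj.system_ref,
        metadata={**traj.metadata, "fitted": True},
    )


@dataclass
class PcaResult:
    """Coordinate-covariance PCA over an analysis selection.

    ``modes`` are orthonormal rows of length 3·n_sel; eigenvalues are the
    per-mode variances in descending order, ``fractions`` their share of the
    total variance (trace of the covariance).
    """

    selection: np.ndarray
    mean_coords: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    fractions: np.ndarray

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def pca_modes(traj: Trajectory, analysis_selection: np.ndarray) -> PcaResult:
    """Eigendecompose the coordinate covariance over the selection.

    The trajectory is expected to be pre-aligned (see
    :func:`fit_superpose_series`).  A trajectory without variance (e.g. one
    frame repeated) yields all-zero eigenvalues with a warning.
    """
    sel = np.asarray(analysis_selection, dtype=int)
    if len(traj) < 2:
        warnings.warn("PCA of fewer than 2 frames: zero covariance", stacklevel=2)
    X = traj.coords_array(sel).reshape(len(traj), -1)
    mean = X.mean(axis=0) if len(traj) else np.zeros(3 * len(sel))
    Xc = X - mean
    n = max(len(traj), 1)
    cov = (Xc.T @ Xc) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    modes = evecs[:, order].T
    total = evals.sum()
    if total > 0:
        fractions = evals / total
    else:
        fractions = np.zeros_like(evals)
        warnings.warn("zero total variance: fractions undefined, reported as 0", stacklevel=2)
    return PcaResult(
        selection=sel,
        mean_coords=mean.reshape(-1, 3),
        modes=modes,
        eigenvalues=evals,
        fractions=fractions,
    )


def project_trajectory(
    traj: Trajectory, pca: PcaResult, n_modes: int = 3
) -> np.ndarray:
    """Project frames onto the leading PCA modes → (n_frames, n_modes).

    The projection of the mean structure is the origin; projecting the
    fitting trajectory itself reproduces per-mode variances equal to the
    eigenvalues, and a full-rank reconstruction recovers the centered data.
    """
    if n_modes > pca.modes.shape[0]:
        raise ValueError(
            f"n_modes={n_modes} exceeds available modes {pca.modes.shape[0]}"
        )
    X = traj.coords_array(pca.selection).reshape(len(traj), -1)
    return (X - pca.mean_coords.ravel()) @ pca.modes[:n_modes].T


def distance_pairs_series(
    traj: Trajectory,
    system: ParticleSystem,
    pairs: Sequence[tuple[str, str]],
) -> dict[str, np.ndarray]:
    """Per-frame Euclidean distances for labeled site pairs.

    Returns ``{"labelA-labelB": series}``; export two series against each
    other for the pair-vs-pair scatter view of conformational states.
    """
    out: dict[str, np.ndarray] = {}
    for la, lb in pairs:
        ia, ib = system.site(la), system.site(lb)
        xs = traj.coords_array()
        out[f"{la}-{lb}"] = np.linalg.norm(xs[:, ia, :] - xs[:, ib, :], axis=1)
    return out


def groupwise_rmsd(
    traj: Trajectory,
    reference: np.ndarray,
    system: ParticleSystem,
    groups: Sequence[str],
    fit_mode: Literal["global_fit", "self_fit"] = "global_fit",
    fit_selection: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-group RMSD series under the two fitting conventions.

    ``global_fit`` superposes each frame on the designated fit selection
    (default: all particles) and then reports each group's RMSD without
    refitting — a displaced-but-rigid group shows its full displacement.
    ``self_fit`` superposes each group on itself first, isolating internal
    deformation from domain motion.
    """
    reference = np.asarray(reference, dtype=float)
    group_idx = {g: system.group(g) for g in groups}
    out = {g: np.empty(len(traj)) for g in groups}
    if fit_mode == "global_fit":
        fit_sel = (
            np.arange(system.n_particles)
            if fit_selection is None
            else np.asarray(fit_selection, dtype=int)
        )
        aligned = fit_superpose_series(traj, reference, fit_sel)
        for k, f in enumerate(aligned):
            for g, idx in group_idx.items():
                d = f.coords[idx] - reference[idx]
                out[g][k] = math.sqrt(float((d**2).sum()) / len(idx))
    elif fit_mode == "self_fit":
        for k, f in enumerate(traj):
            for g, idx in group_idx.items():
                _, _, rmsd = kabsch_superpose(f.coords[idx], reference[idx])
                out[g][k] = rmsd
    else:
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    return out


@dataclass
class ClusterResult:
    representative_index: int
    representative: Frame
    assignments: np.ndarray
    rmsd_matrix: np.ndarray


def cluster_representative(
    frames: Sequence[Frame],
    selection: np.ndarray,
    threshold: float = 1.0,
) -> ClusterResult:
    """Medoid of the largest average-linkage RMSD cluster.

    Pairwise best-fit RMSD over the selection feeds average-linkage
    hierarchical clustering cut at ``threshold``; the representative is the
    medoid (minimal summed RMSD to cluster mates) of the most populated
    cluster.  All ties resolve toward the earliest frame.
    """
    sel = np.asarray(selection, dtype=int)
    n = len(frames)
    if n == 0:
        raise ValueError("need at least one frame")
    coords = [np.asarray(f.coords)[sel] for f in frames]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(coords[i], coords[j])
            dm[i, j] = dm[j, i] = rmsd
    if n == 1:
        assignments = np.array([1])
    else:
        Z = linkage(squareform(dm, checks=False), method="average")
        assignments = fcluster(Z, t=threshold, criterion="distance")
    # Largest cluster; size ties -> the cluster containing the earliest frame.
    labels = np.unique(assignments)
    sizes = {int(lb): int((assignments == lb).sum()) for lb in labels}
    best_label = min(
        sizes, key=lambda lb: (-sizes[lb], int(np.argmax(assignments == lb)))
    )
    members = np.flatnonzero(assignments == best_label)
    sums = dm[np.ix_(members, members)].sum(axis=1)
    rep = int(members[int(np.argmin(sums))])  # argmin takes the earliest on ties
    return ClusterResult(
        representative_index=rep,
        representative=frames[rep],
        assignments=assignments,
        rmsd_matrix=dm,
    )


@dataclass
class CoordinationReport:
    """Ligand shell of a central site and its octahedrality.

    ``cis_deviation``/``trans_deviation`` are the maximal deviations of the
    ligand–center–ligand angles from 90° and 180° after classifying each
    angle to its nearer ideal; ``is_octahedral`` requires exactly six
    ligands, twelve cis and three trans angles, all within tolerance.
    """

    ligand_count: int
    ligand_labels: list[str]
    distances: np.ndarray
    cis_deviation: float
    trans_deviation: float
    is_octahedral: bool


def coordination_geometry(
    frame: Frame | np.ndarray,
    system: ParticleSystem,
    center_label: str,
    candidate_labels: Sequence[str],
    cutoff: float,
    angle_tolerance: float = 15.0,
) -> CoordinationReport:
    """Characterize the coordination shell around a labeled center.

    Candidates within ``cutoff`` of the center are ligands; all
    ligand–center–ligand angles are classified as cis (nearer 90°) or trans
    (nearer 180°).  ``angle_tolerance`` is in degrees.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    center = coords[system.site(center_label)]
    ligands, labels = [], []
    for lb in candidate_labels:
        p = coords[system.site(lb)]
        if float(np.linalg.norm(p - center)) <= cutoff:
            ligands.append(p)
            labels.append(lb)
    distances = np.array([float(np.linalg.norm(p - center)) for p in ligands])
    cis_dev = trans_dev = 0.0
    n_cis = n_trans = 0
    for i in range(len(ligands)):
        for j in range(i + 1, len(ligands)):
            u = ligands[i] - center
            v = ligands[j] - center
            cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if abs(ang - 90.0) <= abs(ang - 180.0):
                n_cis += 1
                cis_dev = max(cis_dev, abs(ang - 90.0))
            else:
                n_trans += 1
                trans_dev = max(trans_dev, abs(ang - 180.0))
    is_oct = (
        len(ligands) == 6
        and n_cis == 12
        and n_trans == 3
        and cis_dev <= angle_tolerance
        and trans_dev <= angle_tolerance
    )
    return CoordinationReport(
        ligand_count=len(ligands),
        ligand_labels=labels,
        distances=distances,
        cis_deviation=cis_dev,
        trans_deviation=trans_dev,
        is_octahedral=is_oct,
    )


def interaction_decomposition(
    system: ParticleSystem,
    frame: Frame | np.ndarray,
    group_a: str,
    group_b: str,
) -> tuple[float, dict[int, float]]:
    """Cross-group non-bonded interaction energy with per-particle split.

    Sums only pairwise short-range terms with one end in each group; each
    pair's energy is shared half-and-half between its endpoints, so the
    per-particle contributions sum to the total exactly.  The groups must be
    disjoint.
    """
    idx_a = set(system.group(group_a).tolist())
    idx_b = set(system.group(group_b).tolist())
    if idx_a & idx_b:
        raise ValueError(f"groups {group_a!r} and {group_b!r} overlap")
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    total = 0.0
    per_particle: dict[int, float] = {}
    for t in system.terms:
        if not isinstance(t, PairWell):
            continue
        crossing = (t.i in idx_a and t.j in idx_b) or (t.i in idx_b and t.j in idx_a)
        if not crossing:
            continue
        r = float(np.linalg.norm(coords[t.i] - coords[t.j]))
        e = t.energy_at(r)
        total += e
        per_particle[t.i] = per_particle.get(t.i, 0.0) + 0.5 * e
        per_particle[t.j] = per_particle.get(t.j, 0.0) + 0.5 * e
    return total, per_particle
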