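"""Frames and trajectories: time-ordered coordinates with optional bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["Frame", "Trajectory"]


@dataclass
class Frame:
    """One snapshot: time, coordinates, and optional velocities/energies.

    ``bias_values`` holds per-channel bias bookkeeping, e.g.
    ``{"amd_internal": ΔV_d, "amd_total": ΔV_P, "tmd": U}``; the accelerated-MD
    reweighting machinery sums the ``amd_*`` entries.
    """

    time: float
    coords: np.ndarray
    velocities: np.ndarray | None = None
    potential_energy: float | None = None
    bias_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError("velocities must match coords shape")

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    def total_bias(self, prefix: str = "amd") -> float:
        """Sum of bias channels whose name starts with ``prefix``."""
        return float(
            sum(v for k, v in self.bias_values.items() if k.startswith(prefix))
        )


@dataclass
class Trajectory:
    """An ordered list of frames from one system.

    Invariants: strictly increasing frame times, uniform particle count.
    """

    frames: list[Frame] = field(default_factory=list)
    system_ref: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        counts = {f.n_particles for f in self.frames}
        if len(counts) > 1:
            raise ValueError(f"inconsistent particle counts {sorted(counts)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self, selection: np.ndarray | None = None) -> np.ndarray:
        """Stack coordinates as (n_frames, n_sel, 3)."""
        if not self.frames:
            return np.zeros((0, 0, 3))
        out = np.stack([f.coords for f in self.frames])
        if selection is not None:
            out = out[:, np.asarray(selection, dtype=int), :]
        return out

    def bias_series(self, prefix: str = "amd") -> np.ndarray:
        return np.array([f.total_bias(prefix) for f in self.frames])
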