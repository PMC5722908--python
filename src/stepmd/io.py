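"""Structure and trajectory I/O.

Structures: minimal fixed-column PDB (ATOM/HETATM records; chain and
occupancy fields are written but ignored on read; 3-decimal Å precision) and
XYZ.  Bead indices are 0-based in memory; the file formats keep their native
1-based serials.

Trajectories: a self-describing text container (``.traj``) — one JSON header
line followed by per-frame blocks:

    #STEPMD-TRAJ 1
    #META {"n_particles": 5, "system_ref": "...", "metadata": {...}}
    FRAME t=<time> pe=<energy|none> vel=<0|1> bias=<json>
    x y z [vx vy vz]        (n_particles lines, 17-significant-digit floats)

Floats are written with repr precision, so coordinate arrays round-trip
bit for bit.  A truncated file raises :class:`TrajectoryParseError` carrying
the number of complete frames recovered.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .trajectory import Frame, Trajectory

__all__ = [
    "StructureParseError",
    "TrajectoryParseError",
    "write_structure",
    "read_structure",
    "write_trajectory",
    "read_trajectory",
]


class StructureParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


class TrajectoryParseError(ValueError):
    def __init__(self, path, lineno: int, message: str, frames_recovered: int):
        super().__init__(
            f"{path}:{lineno}: {message} ({frames_recovered} complete frames recovered)"
        )
        self.lineno = lineno
        self.frames_recovered = frames_recovered


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("pdb", "xyz"):
            raise ValueError(f"unknown structure format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz"):
        return suffix
    raise ValueError(f"cannot infer structure format from {path!r}; pass format=")


def write_structure(
    path,
    coords: np.ndarray,
    names: list[str] | None = None,
    format: str | None = None,
) -> None:
    """Write bead coordinates as PDB or XYZ (format inferred from suffix)."""
    fmt = _infer_format(path, format)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    n = coords.shape[0]
    if names is None:
        names = [f"B{i + 1}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names length must match coords")
    with open(path, "w") as fh:
        if fmt == "xyz":
            fh.write(f"{n}\n")
            fh.write("stepmd beads\n")
            for name, (x, y, z) in zip(names, coords):
                fh.write(f"{name} {x:.10f} {y:.10f} {z:.10f}\n")
        else:
            for i, (name, (x, y, z)) in enumerate(zip(names, coords), start=1):
                atom = name[:4].upper().ljust(4)
                fh.write(
                    f"HETATM{i:5d} {atom} BEA A{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
            fh.write("END\n")


def read_structure(path, format: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a PDB or XYZ structure → (coords, bead names).

    Atom ordering is preserved; malformed records raise
    :class:`StructureParseError` naming the offending line.
    """
    fmt = _infer_format(path, format)
    coords: list[list[float]] = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if fmt == "xyz":
        if not lines:
            raise StructureParseError(path, 1, "empty XYZ file")
        try:
            n = int(lines[0].split()[0])
        except (ValueError, IndexError):
            raise StructureParseError(path, 1, "expected atom count") from None
        if len(lines) < n + 2:
            raise StructureParseError(path, len(lines), f"expected {n} atom records")
        for lineno in range(3, n + 3):
            parts = lines[lineno - 1].split()
            if len(parts) < 4:
                raise StructureParseError(path, lineno, "expected: name x y z")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise StructureParseError(path, lineno, "bad coordinate field") from None
            names.append(parts[0])
            coords.append(xyz)
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    path, lineno, "record too short: missing coordinate columns"
                )
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError:
                raise StructureParseError(path, lineno, "bad coordinate field") from None
            names.append(line[12:16].strip())
            coords.append(xyz)
    return np.array(coords, dtype=float).reshape(-1, 3), names


# --------------------------------------------------------------------------
# Trajectory container
# --------------------------------------------------------------------------

_MAGIC = "#STEPMD-TRAJ 1"


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trajectory(path, traj: Trajectory) -> None:
    """Write the text trajectory container (lossless float round-trip)."""
    n = traj.frames[0].n_particles if traj.frames else 0
    meta = {
        "n_particles": n,
        "system_ref": traj.system_ref,
        "metadata": traj.metadata,
    }
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write("#META " + json.dumps(meta) + "\n")
        for f in traj:
            pe = "none" if f.potential_energy is None else _fmt(f.potential_energy)
            bias = json.dumps(f.bias_values, separators=(",", ":"))
            vel = 1 if f.velocities is not None else 0
            # bias JSON goes last: it is the only field that may contain spaces
            fh.write(f"FRAME t={_fmt(f.time)} pe={pe} vel={vel} bias={bias}\n")
            for i in range(f.n_particles):
                row = [_fmt(v) for v in f.coords[i]]
                if f.velocities is not None:
                    row += [_fmt(v) for v in f.velocities[i]]
                fh.write(" ".join(row) + "\n")


def read_trajectory(path) -> Trajectory:
    """Read the text trajectory container.

    Truncated files raise :class:`TrajectoryParseError` reporting how many
    complete frames were recovered before the defect.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise TrajectoryParseError(path, 1, "missing trajectory magic header", 0)
    if len(lines) < 2 or not lines[1].startswith("#META "):
        raise TrajectoryParseError(path, 2, "missing #META header", 0)
    try:
        meta = json.loads(lines[1][len("#META ") :])
    except json.JSONDecodeError:
        raise TrajectoryParseError(path, 2, "malformed #META JSON", 0) from None
    n = int(meta.get("n_particles", 0))
    frames: list[Frame] = []
    lineno = 2
    while lineno < len(lines):
        header = lines[lineno]
        lineno += 1
        if not header.strip():
            continue
        if not header.startswith("FRAME "):
            raise TrajectoryParseError(
                path, lineno, f"expected FRAME header, got {header[:30]!r}", len(frames)
            )
        try:
            fields = dict(
                kv.split("=", 1) for kv in header[len("FRAME ") :].split(" ", 3)
            )
            t = float(fields["t"])
            pe = None if fields["pe"] == "none" else float(fields["pe"])
            bias = json.loads(fields["bias"])
            has_vel = fields["vel"] == "1"
        except (KeyError, ValueError, json.JSONDecodeError):
            raise TrajectoryParseError(
                path, lineno, "malformed FRAME header", len(frames)
            ) from None
        if lineno + n > len(lines):
            raise TrajectoryParseError(
                path, len(lines), "truncated frame block", len(frames)
            )
        block = lines[lineno : lineno + n]
        lineno += n
        want = 6 if has_vel else 3
        vals = []
        for k, row in enumerate(block):
            parts = row.split()
            if len(parts) != want:
                raise TrajectoryParseError(
                    path,
                    lineno - n + k + 1,
                    f"expected {want} floats per row",
                    len(frames),
                )
            try:
                vals.append([float(v) for v in parts])
            except ValueError:
                raise TrajectoryParseError(
                    path, lineno - n + k + 1, "bad float field", len(frames)
                ) from None
        arr = np.array(vals, dtype=float).reshape(n, want)
        frames.append(
            Frame(
                time=t,
                coords=arr[:, :3],
                velocities=arr[:, 3:] if has_vel else None,
                potential_energy=pe,
                bias_values={k: float(v) for k, v in bias.items()},
            )
        )
    return Trajectory(
        frames=frames,
        system_ref=str(meta.get("system_ref", "")),
        metadata=dict(meta.get("metadata", {})),
    )
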