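"""Fixed-column GRO coordinate files (single- and multi-frame).

Positions are written with 3 decimals (nm) and velocities with 4
decimals (nm/ps), the format's native precision.  Multi-frame
trajectories are stored as appended GRO frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import MoleculeTopology, System, alkane, ion, \
    polarizable_water, standard_water

__all__ = ["GroFrame", "GroParseError", "read_gro", "read_gro_frames",
           "write_gro", "system_from_gro"]


class GroParseError(ValueError):
    """Malformed GRO content; message carries the offending line number."""


@dataclass
class GroFrame:
    title: str
    positions: np.ndarray            # (n,3) nm
    velocities: np.ndarray           # (n,3) nm/ps (zeros if absent)
    has_velocities: bool
    box: np.ndarray                  # (3,) nm
    resids: list = field(default_factory=list)
    resnames: list = field(default_factory=list)
    atomnames: list = field(default_factory=list)

    @property
    def n_atoms(self):
        return self.positions.shape[0]


def write_gro(system: System, path, title: str = "polwater system",
              append: bool = False, wrap: bool = True,
              velocities: bool = True):
    """Write a System as one GRO frame (optionally appended)."""
    mode = "a" if append else "w"
    pos = system.wrapped_positions() if wrap else system.positions
    with open(path, mode) as fh:
        _write_frame(fh, system, pos, title, velocities)


def _write_frame(fh, system, pos, title, velocities):
    fh.write(f"{title}\n{system.n_sites:d}\n")
    k = 0
    for mol_id, (topo, off) in enumerate(system.molecules):
        resid = (mol_id + 1) % 100000
        for s in range(topo.n_sites):
            name = topo.site_types[s]
            atomid = (k + 1) % 100000
            x, y, z = pos[off + s]
            line = (f"{resid:5d}{topo.name[:5]:<5s}{name[:5]:>5s}"
                    f"{atomid:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
            if velocities:
                vx, vy, vz = system.velocities[off + s]
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(line + "\n")
            k += 1
    b = system.box
    fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


def write_trajectory_gro(traj, path):
    """Append every trajectory frame to a multi-frame GRO file."""
    system = traj.system
    with open(path, "w") as fh:
        for t, x, box in zip(traj.times, traj.positions, traj.boxes):
            tmp = system.copy()
            tmp.positions = x
            tmp.box = np.asarray(box)
            wrapped = tmp.wrapped_positions()
            _write_frame(fh, tmp, wrapped, f"t= {t:.3f} ps",
                         velocities=False)


def _parse_frame(lines, start):
    """Parse one frame starting at line index start; returns (frame, next)."""
    i = start
    if i >= len(lines):
        return None, i
    title = lines[i].rstrip("\n")
    if i + 1 >= len(lines):
        raise GroParseError(f"line {i + 2}: missing atom count")
    try:
        n = int(lines[i + 1].split()[0])
    except (ValueError, IndexError):
        raise GroParseError(
            f"line {i + 2}: cannot parse atom count "
            f"{lines[i + 1].strip()!r}") from None
    if len(lines) < i + 3 + n:
        raise GroParseError(
            f"line {i + 2}: atom count {n} exceeds remaining file")
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    has_vel = True
    resids, resnames, atomnames = [], [], []
    for a in range(n):
        ln = lines[i + 2 + a].rstrip("\n")
        lineno = i + 3 + a
        if len(ln) < 44:
            raise GroParseError(f"line {lineno}: atom line too short")
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            atomnames.append(ln[10:15].strip())
            pos[a] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except ValueError:
            raise GroParseError(
                f"line {lineno}: malformed atom record {ln!r}") from None
        if len(ln) >= 68:
            try:
                vel[a] = [float(ln[44:52]), float(ln[52:60]),
                          float(ln[60:68])]
            except ValueError:
                raise GroParseError(
                    f"line {lineno}: malformed velocity fields") from None
        else:
            has_vel = False
    bline = i + 2 + n
    try:
        box = np.array([float(v) for v in lines[bline].split()[:3]])
        if len(box) != 3:
            raise ValueError
    except (ValueError, IndexError):
        raise GroParseError(f"line {bline + 1}: malformed box line") from None
    frame = GroFrame(title, pos, vel, has_vel, box,
                     resids, resnames, atomnames)
    return frame, bline + 1


def read_gro(path) -> GroFrame:
    """Read the first (or only) frame of a GRO file."""
    with open(path) as fh:
        lines = fh.readlines()
    frame, _ = _parse_frame(lines, 0)
    if frame is None:
        raise GroParseError("line 1: empty file")
    return frame


def read_gro_frames(path):
    """All frames of a (possibly multi-frame) GRO file."""
    with open(path) as fh:
        lines = fh.readlines()
    frames = []
    i = 0
    while i < len(lines) and lines[i].strip():
        frame, i = _parse_frame(lines, i)
        frames.append(frame)
    if not frames:
        raise GroParseError("line 1: empty file")
    return frames


# residue name -> molecule topology factory
_RESNAME_TOPO = {
    "PW": polarizable_water,
    "W4": standard_water,
    "NA": lambda: ion("NA"),
    "CL": lambda: ion("CL"),
    "BUT": lambda: alkane(1, "BUT"),
    "OCT": lambda: alkane(2, "OCT"),
    "HEX": lambda: alkane(4, "HEX"),
}


def system_from_gro(frame: GroFrame) -> System:
    """Rebuild a System from a GRO frame using the residue-name registry."""
    system = System(frame.box)
    i = 0
    n = frame.n_atoms
    while i < n:
        resname = frame.resnames[i]
        resid = frame.resids[i]
        try:
            topo: MoleculeTopology = _RESNAME_TOPO[resname]()
        except KeyError:
            raise GroParseError(
                f"unknown residue name {resname!r} at atom {i + 1}") from None
        j = i
        while j < n and frame.resids[j] == resid \
                and frame.resnames[j] == resname:
            j += 1
        if j - i != topo.n_sites:
            raise GroParseError(
                f"residue {resname} at atom {i + 1} has {j - i} atoms, "
                f"expected {topo.n_sites}")
        mol = system.add_molecule(topo, frame.positions[i:j])
        system.velocities[system.molecule_sites(mol)] = frame.velocities[i:j]
        i = j
    return system
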