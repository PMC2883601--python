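"""Trajectory and energy-log containers produced by the engine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EnergyLog", "Trajectory"]


#: canonical energy-log columns; names carry the units
LOG_COLUMNS = [
    "time_ps",
    "E_lj_kJmol", "E_coul_kJmol", "E_bond_kJmol", "E_angle_kJmol",
    "E_field_kJmol", "E_pot_kJmol", "E_kin_kJmol",
    "temperature_K",
    "Pxx_bar", "Pyy_bar", "Pzz_bar", "Pxy_bar", "Pxz_bar", "Pyz_bar",
    "pressure_bar", "volume_nm3",
    "Mx_enm", "My_enm", "Mz_enm",
    "density_kg_m3",
]


@dataclass
class EnergyLog:
    """Per-record thermodynamic log with units encoded in the column names."""

    frame: pd.DataFrame

    def __post_init__(self):
        t = self.frame["time_ps"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("energy-log times must be strictly increasing")

    def __len__(self):
        return len(self.frame)

    def __getitem__(self, col):
        return self.frame[col].to_numpy()

    @property
    def times(self):
        return self.frame["time_ps"].to_numpy()

    def total_dipole(self):
        return self.frame[["Mx_enm", "My_enm", "Mz_enm"]].to_numpy()

    def pressure_tensor(self):
        """(n, 3, 3) symmetric pressure tensors in bar."""
        f = self.frame
        n = len(f)
        P = np.empty((n, 3, 3))
        P[:, 0, 0] = f["Pxx_bar"]
        P[:, 1, 1] = f["Pyy_bar"]
        P[:, 2, 2] = f["Pzz_bar"]
        P[:, 0, 1] = P[:, 1, 0] = f["Pxy_bar"]
        P[:, 0, 2] = P[:, 2, 0] = f["Pxz_bar"]
        P[:, 1, 2] = P[:, 2, 1] = f["Pyz_bar"]
        return P

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))


@dataclass
class Trajectory:
    """Frames of unwrapped positions with box sizes and a linked energy log.

    Positions are unwrapped (molecules whole, displacements continuous);
    analysis routines apply minimum-image arithmetic where needed.  The
    final :class:`~polwater.topology.System` is attached for topology
    lookups (masses, charges, species selections).
    """

    times: np.ndarray               # (F,) ps
    positions: np.ndarray           # (F, n, 3) nm
    boxes: np.ndarray               # (F, 3) nm
    system: object = None
    energy_log: EnergyLog | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        self.boxes = np.asarray(self.boxes, float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(self.boxes <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_frames(self):
        return len(self.times)

    @property
    def n_sites(self):
        return self.positions.shape[1]

    def volumes(self):
        return np.prod(self.boxes, axis=1)
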