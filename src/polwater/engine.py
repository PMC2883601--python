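"""Molecular-dynamics core.

Leapfrog integration with SHAKE-style constraints, Berendsen weak
coupling of temperature and pressure (isotropic, z-only, or independent
z/xy), minimum-image periodic boundaries, a Verlet neighbour list
rebuilt on skin/2 displacement, and an optional uniform electric field
along z.  A time step of 20 fs with coupling constants tau_T = 0.3 ps
and tau_p = 3.0 ps is the production regime of the force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels, units
from .forcefield import ForceField, R_CUT, R_SHIFT_LJ, shift_coefficients
from .logs import EnergyLog, LOG_COLUMNS, Trajectory
from .topology import System

__all__ = [
    "Protocol",
    "ForceReport",
    "LambdaCoupling",
    "compute_forces",
    "apply_constraints",
    "run_md",
    "SingularityError",
    "ConstraintError",
    "IntegrationError",
]

ENSEMBLES = ("NVE", "NVT", "NPT", "NPzAT", "NPzPxyT")


class SingularityError(RuntimeError):
    """Two interaction sites closer than 1e-5 nm."""


class ConstraintError(RuntimeError):
    """Constraint solver failed to converge."""


class IntegrationError(RuntimeError):
    """Kinetic temperature exploded (> 10x target)."""


@dataclass
class Protocol:
    """Run protocol: ensemble, coupling targets, cutoffs, strides, seed."""

    ensemble: str = "NVT"
    dt: float = 0.02                  # ps (20 fs)
    n_steps: int = 1000
    T_target: float = 300.0           # K
    tau_T: float = 0.3                # ps
    P_target: float = 1.0             # bar
    tau_p: float = 3.0                # ps
    compressibility: float = 4.5e-5   # 1/bar
    r_cut: float = R_CUT              # nm
    skin: float = 0.2                 # nm
    field_Ez: float = 0.0             # V/nm, along z
    seed: int = 0
    traj_stride: int = 100            # steps between stored frames
    log_stride: int = 10              # steps between log records
    constraint_tol: float = 1e-6      # nm
    shake_maxiter: int = 100
    rerandomize_interval: int = 0     # steps; 0 = off (Andersen-style)
    remove_com_every: int = 1
    # harmonic umbrella bias on the z centre of mass of one molecule
    bias_molecule: int = -1           # molecule id; -1 = no bias
    bias_center: float = 0.0          # nm
    bias_k: float = 0.0               # kJ mol^-1 nm^-2

    def __post_init__(self):
        if self.ensemble not in ENSEMBLES:
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_T < self.dt or self.tau_p < self.dt:
            raise ValueError("coupling constants must be >= dt")

    def replace(self, **kw) -> "Protocol":
        return replace(self, **kw)


@dataclass
class LambdaCoupling:
    """Soft-core coupling of one tagged solute molecule to its surroundings."""

    solute_molecule: int
    lam: float
    alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")


@dataclass
class ForceReport:
    forces: np.ndarray                    # (n,3) kJ/mol/nm
    energies: dict                        # per-term kJ/mol
    virial: np.ndarray                    # 3x3 kJ/mol
    pressure_tensor: np.ndarray           # 3x3 bar
    dHdl: float = 0.0

    @property
    def potential(self) -> float:
        return float(sum(self.energies.values()))


# ---------------------------------------------------------------------------
# force-field tables
# ---------------------------------------------------------------------------

class _Tables:
    """Per-system flattened parameter tables and pair-list buffers."""

    def __init__(self, system: System, ff: ForceField,
                 coupling: LambdaCoupling | None = None):
        names = sorted(set(system.site_types))
        self.type_index = {t: k for k, t in enumerate(names)}
        nt = len(names)
        self.type_idx = np.array(
            [self.type_index[t] for t in system.site_types], dtype=np.int64)
        self.has_lj = np.array(
            [ff.bead_type(t).has_lj for t in system.site_types], dtype=np.bool_)
        self.c12 = np.zeros((nt, nt))
        self.c6 = np.zeros((nt, nt))
        self.sigma = np.full((nt, nt), 0.47)
        for a in names:
            for b in names:
                ta, tb = ff.bead_type(a), ff.bead_type(b)
                if ta.has_lj and tb.has_lj:
                    p = ff.lookup_lj_params(a, b)
                    ia, ib = self.type_index[a], self.type_index[b]
                    self.c12[ia, ib] = p.c12
                    self.c6[ia, ib] = p.c6
                    self.sigma[ia, ib] = p.sigma
        self.charges = system.charges.copy()
        self.coul_pref = units.F_ELEC / ff.eps_r
        # exclusion lists (store only j > i)
        n = system.n_sites
        excl = [[] for _ in range(n)]
        for i, j in system.exclusions:
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            excl[a].append(b)
        ptr = np.zeros(n + 1, dtype=np.int64)
        for i in range(n):
            ptr[i + 1] = ptr[i] + len(excl[i])
        idx = np.array([j for row in excl for j in row],
                       dtype=np.int64).reshape(-1)
        self.excl_ptr = ptr
        self.excl_idx = idx
        # solute mask for soft-core coupling
        self.solute_mask = np.zeros(n, dtype=np.bool_)
        if coupling is not None:
            self.solute_mask[system.molecule_sites(
                coupling.solute_molecule)] = True
        # pair-list buffers (grown on demand)
        self._alloc(max(64, 40 * n))

    def _alloc(self, cap):
        self.lj_ij = np.empty((cap, 2), dtype=np.int64)
        self.lj_c12 = np.empty(cap)
        self.lj_c6 = np.empty(cap)
        self.q_ij = np.empty((cap, 2), dtype=np.int64)
        self.q_qq = np.empty(cap)
        self.cpl_ij = np.empty((max(cap // 8, 64), 2), dtype=np.int64)

    def build(self, pos, box, rlist2):
        """(Re)build the pair lists; returns (n_lj, n_q, n_coupled)."""
        while True:
            n_lj, n_q, n_cpl = _kernels.build_pairs(
                pos, box, rlist2, self.has_lj, self.charges, self.type_idx,
                self.c12, self.c6, self.coul_pref, self.excl_ptr,
                self.excl_idx, self.solute_mask, self.lj_ij, self.lj_c12,
                self.lj_c6, self.q_ij, self.q_qq, self.cpl_ij)
            if n_lj >= 0:
                return n_lj, n_q, n_cpl
            self._alloc(2 * self.lj_ij.shape[0])


def _shift_consts(r_cut: float):
    A12, B12, C12 = shift_coefficients(12, R_SHIFT_LJ, r_cut)
    A6, B6, C6 = shift_coefficients(6, R_SHIFT_LJ, r_cut)
    A1, B1, C1 = shift_coefficients(1, 0.0, r_cut)
    return A12, B12, C12, A6, B6, C6, A1, B1, C1


def _evaluate(pos, box, system, tab, counts, r_cut,
              coupling: LambdaCoupling | None, field_Ez: float):
    """Forces, per-term energies, virial for one configuration."""
    n_lj, n_q, n_cpl = counts
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    A12, B12, C12, A6, B6, C6, A1, B1, C1 = _shift_consts(r_cut)
    e_lj, err = _kernels.lj_pair_forces(
        pos, box, n_lj, tab.lj_ij, tab.lj_c12, tab.lj_c6,
        R_SHIFT_LJ, r_cut, A12, B12, C12, A6, B6, C6, forces, virial)
    if err >= 0:
        i, j = tab.lj_ij[err]
        raise SingularityError(f"sites {i} and {j} closer than 1e-5 nm")
    e_coul, err = _kernels.coulomb_pair_forces(
        pos, box, n_q, tab.q_ij, tab.q_qq, r_cut, A1, B1, C1,
        forces, virial)
    if err >= 0:
        i, j = tab.q_ij[err]
        raise SingularityError(f"sites {i} and {j} closer than 1e-5 nm")
    # the pair kernels fill the upper triangle only (pair virial symmetric)
    virial[1, 0] = virial[0, 1]
    virial[2, 0] = virial[0, 2]
    virial[2, 1] = virial[1, 2]
    sc = (A12, B12, C12, A6, B6, C6, A1, B1, C1)
    dhdl = 0.0
    if coupling is not None and n_cpl:
        cpairs = tab.cpl_ij[:n_cpl]
        e_sc, dhdl, err = _kernels.softcore_forces(
            pos, box, cpairs, tab.type_idx, tab.c12, tab.c6, tab.has_lj,
            tab.charges, tab.coul_pref, coupling.lam, coupling.alpha,
            tab.sigma, 0.47, R_SHIFT_LJ, r_cut, *sc, forces, virial)
        if err >= 0:
            i, j = cpairs[err]
            raise SingularityError(
                f"coupled sites {i} and {j} at the soft-core singularity")
        e_lj += e_sc          # soft-core term reported with the LJ channel
    e_bond = _kernels.bond_forces(pos, system.bonds, system.bond_params,
                                  forces, virial)
    e_angle = _kernels.angle_forces(pos, system.angles, system.angle_params,
                                    forces, virial)
    e_field = 0.0
    if field_Ez != 0.0:
        fz = tab.charges * field_Ez * units.FIELD_CONV
        forces[:, 2] += fz
        e_field = -float(fz @ pos[:, 2])
    energies = {"lj": e_lj, "coulomb": e_coul, "bond": e_bond,
                "angle": e_angle, "field": e_field}
    return forces, energies, virial, dhdl


def compute_forces(system: System, ff: ForceField,
                   protocol: Protocol | None = None,
                   coupling: LambdaCoupling | None = None) -> ForceReport:
    """One-shot force/energy/virial evaluation of a configuration.

    The pressure tensor combines the kinetic term from the system's
    current velocities with the pair/bonded virial:
    P_ab = (sum_i m_i v_ia v_ib + sum_pairs r_ab f_b) / V, in bar.
    """
    protocol = protocol or Protocol()
    tab = _Tables(system, ff, coupling)
    rlist = protocol.r_cut + protocol.skin
    counts = tab.build(system.positions, system.box, rlist * rlist)
    forces, energies, virial, dhdl = _evaluate(
        system.positions, system.box, system, tab, counts,
        protocol.r_cut, coupling, protocol.field_Ez)
    kin = (system.velocities * system.masses[:, None]).T @ system.velocities
    ptens = (kin + virial) / system.volume * units.BAR_PER_KJ_NM3
    return ForceReport(forces, energies, virial, ptens, dhdl)


def apply_constraints(ref_positions, new_positions, system: System,
                      tol: float = 1e-6, maxiter: int = 100):
    """Project new_positions onto the constraint manifold (SHAKE).

    Returns the corrected positions; raises :class:`ConstraintError`
    (naming the molecule) on non-convergence.
    """
    out = np.array(new_positions, dtype=float, copy=True)
    invm = 1.0 / system.masses
    niter, _ = _kernels.shake(np.asarray(ref_positions, float), out,
                              system.constraints, system.constraint_lengths,
                              invm, tol, maxiter)
    if niter < 0:
        d = np.linalg.norm(out[system.constraints[:, 0]]
                           - out[system.constraints[:, 1]], axis=1)
        bad = int(np.argmax(np.abs(d - system.constraint_lengths)))
        mol = int(system.site_molecule[system.constraints[bad, 0]])
        raise ConstraintError(
            f"constraints did not converge after {maxiter} iterations "
            f"(molecule {mol})")
    return out


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def run_md(system: System, ff: ForceField, protocol: Protocol,
           coupling: LambdaCoupling | None = None):
    """Integrate the system; returns (final System, Trajectory, EnergyLog).

    Leapfrog positions/velocities with constraints enforced every step,
    Berendsen velocity scaling toward T_target (except NVE), Berendsen
    box scaling for the pressure-coupled ensembles, and centre-of-mass
    motion removal.  Fully reproducible for a given protocol seed.
    """
    p = protocol
    box = system.box.copy()
    if p.r_cut + p.skin >= box.min() / 2.0:
        raise ValueError(
            f"r_cut + skin = {p.r_cut + p.skin} nm must be smaller than "
            f"half the smallest box edge ({box.min() / 2.0:.3f} nm)")

    tab = _Tables(system, ff, coupling)
    pos = system.positions.copy()
    vel = system.velocities.copy()
    masses = system.masses
    invm = 1.0 / masses
    total_mass = masses.sum()
    ndof = max(3 * system.n_sites - len(system.constraints) - 3, 1)
    rng = np.random.default_rng(p.seed)
    rlist2 = (p.r_cut + p.skin) ** 2
    half_skin2 = (0.5 * p.skin) ** 2

    counts = tab.build(pos, box, rlist2)
    pos_build = pos.copy()
    pos_buf = np.empty_like(pos)
    vel_buf = np.empty_like(vel)
    kin = np.empty((3, 3))

    bias_on = p.bias_molecule >= 0 and p.bias_k > 0
    if bias_on:
        bias_sites = system.molecule_sites(p.bias_molecule)
        bias_w = masses[bias_sites] / masses[bias_sites].sum()

    records = []
    frames_t, frames_x, frames_b = [], [], []

    def log_record(t, energies, e_kin, T, ptens, dhdl, bias_z):
        M = tab.charges @ pos
        vol = float(np.prod(box))
        dens = units.amu_per_nm3_to_kg_m3(total_mass / vol)
        rec = [t, energies["lj"], energies["coulomb"], energies["bond"],
               energies["angle"], energies["field"],
               sum(energies.values()), e_kin, T,
               ptens[0, 0], ptens[1, 1], ptens[2, 2],
               ptens[0, 1], ptens[0, 2], ptens[1, 2],
               np.trace(ptens) / 3.0, vol, M[0], M[1], M[2], dens]
        if coupling is not None:
            rec.append(dhdl)
        if bias_on:
            rec.append(bias_z)
        records.append(rec)

    couple_T = p.ensemble != "NVE"
    couple_P = p.ensemble in ("NPT", "NPzAT", "NPzPxyT")
    e_kin0 = 0.5 * float(np.sum(masses[:, None] * vel ** 2))
    T_prev = 2.0 * e_kin0 / (ndof * units.KB)

    for step in range(p.n_steps):
        if _kernels.max_displacement2(pos, pos_build) > half_skin2:
            counts = tab.build(pos, box, rlist2)
            pos_build = pos.copy()

        forces, energies, virial, dhdl = _evaluate(
            pos, box, system, tab, counts, p.r_cut, coupling,
            p.field_Ez)

        bias_z = 0.0
        if bias_on:
            bias_z = float(bias_w @ pos[bias_sites, 2])
            dz = bias_z - p.bias_center
            energies["field"] += 0.5 * p.bias_k * dz * dz
            forces[bias_sites, 2] -= p.bias_k * dz * bias_w

        # leapfrog update; the weak-coupling scale uses the
        # post-constraint temperature of the previous step
        lam_T = 1.0
        if couple_T and T_prev > 0:
            lam_T = np.sqrt(max(0.64, min(
                1.5625, 1.0 + p.dt / p.tau_T * (p.T_target / T_prev - 1.0))))
        _kernels.leapfrog(pos, vel, forces, invm, p.dt, lam_T,
                          pos_buf, vel_buf)
        pos_new = pos_buf
        vel_new = vel_buf

        # constraints: correct positions, fold corrections into the
        # velocities, accumulate the constraint-force virial
        if len(system.constraints):
            niter = _kernels.shake_step(
                pos, pos_new, vel_new, system.constraints,
                system.constraint_lengths, invm, p.constraint_tol,
                p.shake_maxiter, p.dt, virial)
            if niter < 0:
                raise ConstraintError(
                    f"constraints did not converge at step {step}")

        remove_com = bool(p.remove_com_every
                          and (step % p.remove_com_every) == 0)
        e_kin = _kernels.kinetic_and_com(vel_new, masses, total_mass,
                                         remove_com, kin)
        T_inst = 2.0 * e_kin / (ndof * units.KB)
        T_prev = T_inst
        if couple_T and T_inst > 10.0 * p.T_target:
            raise IntegrationError(
                f"temperature blew up: {T_inst:.0f} K at step {step}")

        vol = float(np.prod(box))
        ptens = (kin + virial) / vol * units.BAR_PER_KJ_NM3

        # Berendsen pressure coupling
        if couple_P:
            fac = p.compressibility * p.dt / p.tau_p
            mu = np.ones(3)
            if p.ensemble == "NPT":
                P_iso = float(np.trace(ptens)) / 3.0
                mu[:] = (1.0 - fac * (p.P_target - P_iso)) ** (1.0 / 3.0)
            elif p.ensemble == "NPzAT":
                mu[2] = 1.0 - fac * (p.P_target - ptens[2, 2])
            else:  # NPzPxyT
                mu[2] = 1.0 - fac * (p.P_target - ptens[2, 2])
                mu_xy = (1.0 - fac * (p.P_target
                                      - 0.5 * (ptens[0, 0] + ptens[1, 1])
                                      )) ** 0.5
                mu[0] = mu[1] = mu_xy
            np.clip(mu, 0.98, 1.02, out=mu)
            box *= mu
            pos_new *= mu
            pos_build *= mu

        # Andersen-style resampling (optional; canonical kicks for tiny systems)
        if p.rerandomize_interval and (step + 1) % p.rerandomize_interval == 0:
            sigma = np.sqrt(units.KB * p.T_target / masses)
            vel_new = rng.normal(size=vel_new.shape) * sigma[:, None]
            vel_new -= (masses @ vel_new) / total_mass

        pos, pos_buf = pos_new, pos
        vel, vel_buf = vel_new, vel
        t_now = (step + 1) * p.dt

        if (step + 1) % p.log_stride == 0:
            log_record(t_now, energies, e_kin, T_inst, ptens, dhdl, bias_z)
        if (step + 1) % p.traj_stride == 0:
            frames_t.append(t_now)
            frames_x.append(pos.copy())
            frames_b.append(box.copy())

    final = system.copy()
    final.positions = pos
    final.velocities = vel
    final.box = box.copy()

    cols = list(LOG_COLUMNS)
    if coupling is not None:
        cols.append("dHdl_kJmol")
    if bias_on:
        cols.append("bias_coord_nm")
    log = EnergyLog(pd.DataFrame(records, columns=cols))
    if not frames_t:
        frames_t = [p.n_steps * p.dt]
        frames_x = [pos.copy()]
        frames_b = [box.copy()]
    traj = Trajectory(np.asarray(frames_t), np.asarray(frames_x),
                      np.asarray(frames_b), system=final, energy_log=log,
                      metadata={"protocol": p, **system.metadata})
    return final, traj, log
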