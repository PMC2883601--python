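"""Property estimators for bulk and interfacial coarse-grained water.

Implements the estimators used to parameterise and test the polarizable
water bead: mass density, dielectric constant from total-dipole
fluctuations, per-bead dipole statistics, radial distribution functions,
surface tension from the pressure-tensor anisotropy of a slab, diffusion
from mean-square displacement (with the x4 effective-time convention of
coarse-grained kinetics), and charge-density/electrostatic-potential
profiles.

Statistical errors come from block averaging (>= 5 blocks by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import units
from .logs import EnergyLog, Trajectory

__all__ = [
    "block_average",
    "bead_dipole",
    "max_bead_dipole",
    "DipoleStats",
    "dipole_stats",
    "dielectric_constant",
    "mass_density",
    "rdf",
    "surface_tension",
    "diffusion_coefficient",
    "potential_profile",
    "detect_water_pore",
]


def block_average(x, n_blocks: int = 5):
    """Mean and block-averaged standard error of a correlated series."""
    x = np.asarray(x, float)
    n = len(x)
    if n == 0:
        raise ValueError("empty series")
    nb = min(n_blocks, n)
    blocks = np.array_split(x, nb)
    means = np.array([b.mean() for b in blocks])
    err = means.std(ddof=1) / np.sqrt(nb) if nb > 1 else 0.0
    return float(x.mean()), float(err)


def _energy_log(obj) -> EnergyLog:
    if isinstance(obj, EnergyLog):
        return obj
    if isinstance(obj, Trajectory):
        if obj.energy_log is None:
            raise ValueError("trajectory has no linked energy log")
        return obj.energy_log
    raise TypeError(f"expected Trajectory or EnergyLog, got {type(obj)}")


# ---------------------------------------------------------------------------
# dipoles
# ---------------------------------------------------------------------------

def bead_dipole(wp_pos, wm_pos, q: float = 0.46):
    """Dipole vector (e nm) and magnitude (Debye) of one water bead.

    mu = q (r_WP - r_WM); the magnitude ranges from 0 (satellites
    coincident) to 2 q l when they are antipodal.
    """
    mu = q * (np.asarray(wp_pos, float) - np.asarray(wm_pos, float))
    mag = float(np.linalg.norm(mu)) * units.DEBYE_PER_E_NM
    return mu, mag


def max_bead_dipole(q: float = 0.46, l: float = 0.14) -> float:
    """Maximum attainable bead dipole 2 q l, in Debye."""
    return 2.0 * q * l * units.DEBYE_PER_E_NM


@dataclass
class DipoleStats:
    magnitudes_debye: np.ndarray
    mean_debye: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def dipole_stats(traj: Trajectory, bins: int = 62,
                 q: float = 0.46, l: float = 0.14) -> DipoleStats:
    """Per-bead dipole-magnitude distribution over all frames (Debye)."""
    trips = traj.system.water_site_triplets()
    if len(trips) == 0:
        raise ValueError("no polarizable water in this system")
    mags = []
    for x in traj.positions:
        mu = q * (x[trips[:, 1]] - x[trips[:, 2]])
        mags.append(np.linalg.norm(mu, axis=1) * units.DEBYE_PER_E_NM)
    mags = np.concatenate(mags)
    dmax = 2.0 * q * l * units.DEBYE_PER_E_NM
    counts, edges = np.histogram(mags, bins=bins, range=(0.0, dmax * 1.001))
    return DipoleStats(mags, float(mags.mean()), counts, edges)


def dielectric_constant(traj, T: float, n_blocks: int = 5):
    """Dielectric constant from total-dipole fluctuations, with block error.

    eps = 1 + (<M^2> - <M>^2) / (3 eps0 V kB T), the no-reaction-field
    (eps_rf = infinity) limit of the Clausius-Mosotti-type fluctuation
    relation.  The run-time Coulomb screening constant does not enter.
    """
    log = _energy_log(traj)
    if len(log) < 2:
        raise ValueError("need at least 2 logged frames with total dipole")
    M = log.total_dipole()
    V = log["volume_nm3"]
    if np.any(V <= 0):
        raise ValueError("non-positive frame volume")

    def eps_of(Mb, Vb):
        fluct = np.sum(Mb.var(axis=0))
        return 1.0 + fluct / (3.0 * units.EPS0 * Vb.mean() * units.KB * T)

    eps = eps_of(M, V)
    nb = min(n_blocks, len(log) // 2) or 1
    idx = np.array_split(np.arange(len(log)), nb)
    if nb > 1:
        per_block = np.array([eps_of(M[k], V[k]) for k in idx])
        err = per_block.std(ddof=1) / np.sqrt(nb)
    else:
        err = 0.0
    return float(eps), float(err)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def mass_density(traj, n_blocks: int = 5):
    """Mean mass density (kg/m^3) over the run, with block error."""
    if isinstance(traj, Trajectory) and traj.energy_log is None:
        mass = traj.system.total_mass
        dens = units.amu_per_nm3_to_kg_m3(mass / traj.volumes())
    else:
        dens = _energy_log(traj)["density_kg_m3"]
    return block_average(dens, n_blocks)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def rdf(traj: Trajectory, species_a: str, species_b: str,
        bin_width: float = 0.02, r_max: float | None = None):
    """Shell-normalised radial distribution function g(r).

    Minimum-image distances; for identical selections self-pairs are
    excluded.  Returns (bin centres nm, g).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sel_a = traj.system.select(species_a)
    sel_b = traj.system.select(species_b)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("empty species selection")
    same = species_a == species_b
    if r_max is None:
        r_max = float(traj.boxes.min()) / 2.0
    if r_max > traj.boxes.min() / 2.0 + 1e-9:
        raise ValueError("r_max exceeds half the smallest box edge")
    nbins = int(np.ceil(r_max / bin_width))
    counts = np.zeros(nbins)
    norm = 0.0
    for x, box in zip(traj.positions, traj.boxes):
        d = x[sel_a][:, None, :] - x[sel_b][None, :, :]
        d -= box * np.rint(d / box)
        r = np.sqrt((d ** 2).sum(axis=2))
        if same:
            np.fill_diagonal(r, np.inf)
        h, _ = np.histogram(r, bins=nbins, range=(0.0, r_max))
        counts += h
        vol = float(np.prod(box))
        npairs = len(sel_a) * (len(sel_b) - 1 if same else len(sel_b))
        norm += npairs / vol
    edges = np.linspace(0.0, r_max, nbins + 1)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (norm * shell)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


# ---------------------------------------------------------------------------
# surface tension
# ---------------------------------------------------------------------------

def surface_tension(traj: Trajectory, n_blocks: int = 5):
    """Surface tension of a z-normal slab (mN/m), with block error.

    gamma = (L_z / 2) (<P_zz> - <(P_xx + P_yy)/2>); the factor 2 accounts
    for the two interfaces of a periodic slab.
    """
    if traj.metadata.get("kind", "slab") != "slab":
        raise ValueError("surface tension requires a slab system "
                         "(normal along z)")
    log = _energy_log(traj)
    area = float(traj.boxes[-1, 0] * traj.boxes[-1, 1])
    lz = log["volume_nm3"] / area
    gam = 0.5 * lz * (log["Pzz_bar"]
                      - 0.5 * (log["Pxx_bar"] + log["Pyy_bar"]))
    gam_mn_m = gam * units.MN_PER_M_PER_BAR_NM
    return block_average(gam_mn_m, n_blocks)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def diffusion_coefficient(traj: Trajectory, fit_window_ps: float,
                          effective_time_factor: float = 4.0,
                          species: str = "W"):
    """Self-diffusion from the MSD slope over effective time (cm^2/s).

    Multiple time origins with stride = fit window / 10.  The CG clock
    runs ~4x fast, so kinetic quantities are reported against effective
    time t_eff = factor * t; returns a dict with the per-bead coefficient
    ``D_cg`` and the individual-molecule value ``D_molecular`` =
    factor * D_cg, both in cm^2/s, plus the factor used.
    """
    times = traj.times
    if fit_window_ps <= 0:
        raise ValueError("fit window must be positive")
    span = times[-1] - times[0]
    if fit_window_ps > span:
        raise ValueError(
            f"fit window {fit_window_ps} ps exceeds trajectory span "
            f"{span:.1f} ps")
    sel = traj.system.select(species)
    if len(sel) == 0:
        raise ValueError(f"no sites of species {species!r}")
    x = traj.positions[:, sel, :]
    # heal periodic jumps: cumulative minimum-image frame-to-frame steps
    d = np.diff(x, axis=0)
    d -= traj.boxes[1:, None, :] * np.rint(d / traj.boxes[1:, None, :])
    x = np.concatenate([x[:1], x[:1] + np.cumsum(d, axis=0)])
    dt_frame = float(np.mean(np.diff(times)))
    n_win = max(2, int(round(fit_window_ps / dt_frame)))
    stride = max(1, n_win // 10)
    n_frames = len(times)
    msd = np.zeros(n_win + 1)
    counts = np.zeros(n_win + 1)
    for o in range(0, n_frames - n_win, stride):
        disp = x[o:o + n_win + 1] - x[o]
        msd_o = (disp ** 2).sum(axis=2).mean(axis=1)
        msd += msd_o
        counts += 1
    if counts[0] == 0:
        raise ValueError("trajectory too short for the requested window")
    msd /= counts
    tau = np.arange(n_win + 1) * dt_frame * effective_time_factor
    # least-squares slope through the window (skip the t=0 point)
    A = np.vstack([tau[1:], np.ones(n_win)]).T
    slope, _ = np.linalg.lstsq(A, msd[1:], rcond=None)[0]
    d_cg = slope / 6.0 * units.CM2_S_PER_NM2_PS
    return {
        "D_cg": float(d_cg),
        "D_molecular": float(effective_time_factor * d_cg),
        "effective_time_factor": float(effective_time_factor),
        "msd_nm2": msd,
        "t_eff_ps": tau,
    }


# ---------------------------------------------------------------------------
# electrostatics profiles
# ---------------------------------------------------------------------------

def potential_profile(traj: Trajectory, axis: str = "z",
                      bin_width: float = 0.1):
    """Charge density rho(z) (e/nm^3) and potential phi(z) (V) along an axis.

    phi from double integration of the averaged charge density with
    phi = dphi/dz = 0 at the lower box face.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise ValueError(f"unknown axis {axis!r}")
    if traj.metadata.get("kind") == "slab" and \
            traj.metadata.get("slab_axis", "z") != axis:
        raise ValueError("axis is not the slab normal")
    q = traj.system.charges
    L = float(traj.boxes[:, ax].mean())
    nbins = max(2, int(round(L / bin_width)))
    edges = np.linspace(0.0, L, nbins + 1)
    rho = np.zeros(nbins)
    for x, box in zip(traj.positions, traj.boxes):
        z = x[:, ax] - box[ax] * np.floor(x[:, ax] / box[ax])
        h, _ = np.histogram(z, bins=edges, weights=q)
        area = np.prod(box) / box[ax]
        rho += h / (area * (edges[1] - edges[0]))
    rho /= traj.n_frames
    centers = 0.5 * (edges[1:] + edges[:-1])
    # d^2 phi / dz^2 = -rho / eps0  (explicit charges only)
    efield = cumulative_trapezoid(rho, centers, initial=0.0) / units.EPS0
    phi_kj_e = -cumulative_trapezoid(efield, centers, initial=0.0)
    phi_volt = phi_kj_e / units.FIELD_CONV
    return centers, rho, phi_volt


# ---------------------------------------------------------------------------
# pore detection
# ---------------------------------------------------------------------------

def detect_water_pore(system, linkage_cutoff: float = 0.6,
                      margin: float = 0.3):
    """Check for a continuous water pathway across an alkane slab.

    Water LJ centres inside (and just beyond) the z-range of the alkane
    C1 sites are clustered by single linkage at the given cutoff
    (periodic minimum image); a cluster touching both interfaces counts
    as a pore.  Returns (pore_found, n_bridging_waters).
    """
    w = system.select("W")
    c = system.select("C1")
    if len(w) == 0 or len(c) == 0:
        raise ValueError("pore detection needs water and alkane sites")
    box = system.box
    pos = system.wrapped_positions()
    zlo = float(pos[c, 2].min())
    zhi = float(pos[c, 2].max())
    inside = w[(pos[w, 2] >= zlo - margin) & (pos[w, 2] <= zhi + margin)]
    if len(inside) == 0:
        return False, 0
    x = pos[inside]
    d = x[:, None, :] - x[None, :, :]
    d -= box * np.rint(d / box)
    r = np.sqrt((d ** 2).sum(axis=2))
    adj = coo_matrix(r < linkage_cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    for k in range(n_comp):
        z = x[labels == k, 2]
        if z.min() <= zlo + margin / 3 and z.max() >= zhi - margin / 3:
            return True, int((labels == k).sum())
    return False, 0
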