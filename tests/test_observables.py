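"""Property estimators: closed-form oracles and unit round-trips."""

import numpy as np
import pandas as pd
import pytest

import polwater.observables as obs
from polwater import units
from polwater.logs import EnergyLog, LOG_COLUMNS, Trajectory


def _synthetic_log(times, M, volume, ptens=None, mass_amu=72.0):
    """Minimal energy log with given total dipoles / volumes / pressures."""
    n = len(times)
    M = np.asarray(M, float).reshape(n, 3)
    vol = np.broadcast_to(np.asarray(volume, float), (n,))
    df = pd.DataFrame(0.0, index=range(n), columns=LOG_COLUMNS)
    df["time_ps"] = times
    df[["Mx_enm", "My_enm", "Mz_enm"]] = M
    df["volume_nm3"] = vol
    df["density_kg_m3"] = units.amu_per_nm3_to_kg_m3(mass_amu / vol)
    if ptens is not None:
        df[["Pxx_bar", "Pyy_bar", "Pzz_bar"]] = ptens
    return EnergyLog(df)


# ---------------------------------------------------------------------------
# dipoles
# ---------------------------------------------------------------------------

def test_bead_dipole_zero_and_max():
    w = np.zeros(3)
    _, mag = obs.bead_dipole(w, w)
    assert mag == 0.0
    wp = np.array([0.14, 0, 0])
    wm = np.array([-0.14, 0, 0])
    _, mag = obs.bead_dipole(wp, wm)
    assert round(mag, 1) == 6.2                 # 2 q l for q=0.46, l=0.14


def test_dipole_unit_conversion_alignment():
    """Four aligned 2.35 D dipoles sum to 9.4 D."""
    one = 2.35 / units.DEBYE_PER_E_NM           # e nm
    total = 4 * one * units.DEBYE_PER_E_NM
    assert round(total, 1) == 9.4


def test_dipole_bound_in_simulation(short_nvt):
    _, traj, _ = short_nvt
    st = obs.dipole_stats(traj)
    assert st.magnitudes_debye.max() <= 6.2 + 0.01
    assert st.magnitudes_debye.min() >= 0.0


# ---------------------------------------------------------------------------
# dielectric constant
# ---------------------------------------------------------------------------

def test_dielectric_no_fluctuation_is_vacuum():
    log = _synthetic_log(np.arange(1, 11.0), np.zeros((10, 3)), 50.0)
    eps, err = obs.dielectric_constant(log, 300.0)
    assert eps == pytest.approx(1.0)
    assert err == 0.0


def test_dielectric_gaussian_closed_form(rng):
    """i.i.d. Gaussian M recovers eps = 1 + 3 s^2/(3 eps0 V kB T)."""
    s2 = 4.0
    V, T, n = 50.0, 300.0, 40000
    M = rng.normal(scale=np.sqrt(s2), size=(n, 3))
    log = _synthetic_log(np.arange(1.0, n + 1), M, V)
    eps, err = obs.dielectric_constant(log, T)
    expected = 1.0 + 3 * s2 / (3 * units.EPS0 * V * units.KB * T)
    assert eps == pytest.approx(expected, rel=0.03)


def test_dielectric_needs_frames_and_volume():
    log = _synthetic_log([1.0], np.zeros((1, 3)), 50.0)
    with pytest.raises(ValueError):
        obs.dielectric_constant(log, 300.0)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def test_mass_density_hand_arithmetic():
    # 400 beads x 72 amu in a (3.634 nm)^3 box -> the build density
    vol = 3.634 ** 3
    log = _synthetic_log(np.arange(1, 6.0), np.zeros((5, 3)), vol,
                         mass_amu=400 * 72.0)
    rho, err = obs.mass_density(log)
    expected = 400 * 72.0 * units.AMU_KG * 1e27 / vol
    assert rho == pytest.approx(expected, rel=1e-12)
    assert rho == pytest.approx(996.5, abs=0.5)
    assert err == pytest.approx(0.0, abs=1e-9)


def test_density_constant_under_nvt(short_nvt):
    _, _, log = short_nvt
    d = log["density_kg_m3"]
    assert np.ptp(d) < 1e-9


# ---------------------------------------------------------------------------
# rdf
# ---------------------------------------------------------------------------

def _point_trajectory(points_per_frame, box, site_type="P4"):
    from polwater.topology import System, standard_water
    frames = np.asarray(points_per_frame, float)
    system = System(np.asarray(box, float))
    for c in frames[0]:
        system.add_molecule(standard_water(), c.reshape(1, 3))
    times = np.arange(1.0, len(frames) + 1)
    boxes = np.tile(box, (len(frames), 1))
    return Trajectory(times, frames, boxes, system=system)


def test_rdf_uniform_ideal_gas(rng):
    box = np.array([5.0, 5.0, 5.0])
    pts = rng.uniform(0, 5.0, size=(40, 300, 3))
    traj = _point_trajectory(pts, box)
    r, g = obs.rdf(traj, "P4", "P4", bin_width=0.1)
    sel = r > 0.4                    # small-r bins are noise-dominated
    assert abs(g[sel].mean() - 1.0) < 0.02
    assert np.max(np.abs(g[sel] - 1.0)) < 0.15


def test_rdf_two_fixed_particles():
    box = np.array([4.0, 4.0, 4.0])
    pts = np.array([[[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]])
    traj = _point_trajectory(pts, box)
    r, g = obs.rdf(traj, "P4", "P4", bin_width=0.05)
    occupied = np.nonzero(g)[0]
    assert len(occupied) == 1
    assert r[occupied[0]] == pytest.approx(0.525, abs=0.026)


def test_rdf_argument_errors(short_nvt):
    _, traj, _ = short_nvt
    with pytest.raises(ValueError):
        obs.rdf(traj, "W", "W", bin_width=-0.1)
    with pytest.raises(ValueError):
        obs.rdf(traj, "W", "W", r_max=10.0)


# ---------------------------------------------------------------------------
# surface tension
# ---------------------------------------------------------------------------

def _slab_traj_with_pressure(ptens, lz=10.0):
    n = len(ptens)
    times = np.arange(1.0, n + 1)
    boxes = np.tile([4.0, 4.0, lz], (n, 1))
    log = _synthetic_log(times, np.zeros((n, 3)), 4.0 * 4.0 * lz,
                         ptens=ptens)
    traj = Trajectory(times, np.zeros((n, 1, 3)), boxes, energy_log=log,
                      metadata={"kind": "slab"})
    return traj


def test_surface_tension_isotropic_zero():
    ptens = np.tile([2.0, 2.0, 2.0], (8, 1))
    gam, err = obs.surface_tension(_slab_traj_with_pressure(ptens))
    assert gam == pytest.approx(0.0, abs=1e-12)


def test_surface_tension_hand_arithmetic():
    # Pzz = 1 bar, Pxx = Pyy = -1 bar, Lz = 10 nm -> 10 bar nm -> 1.0 mN/m
    ptens = np.tile([-1.0, -1.0, 1.0], (8, 1))
    gam, err = obs.surface_tension(_slab_traj_with_pressure(ptens))
    assert gam == pytest.approx(1.0, rel=1e-12)


def test_surface_tension_requires_slab():
    traj = _slab_traj_with_pressure(np.tile([0.0, 0.0, 0.0], (4, 1)))
    traj.metadata["kind"] = "bulk"
    with pytest.raises(ValueError):
        obs.surface_tension(traj)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def test_diffusion_frozen_is_zero():
    box = np.array([5.0, 5.0, 5.0])
    pts = np.tile(np.array([[1.0, 1, 1], [3.0, 3, 3]]), (50, 1, 1))
    traj = _point_trajectory(pts, box)
    d = obs.diffusion_coefficient(traj, fit_window_ps=20.0,
                                  species="P4")
    assert d["D_cg"] == pytest.approx(0.0, abs=1e-15)


def test_diffusion_brownian_walk(rng):
    """Recover the generating D of a random walk within 5%."""
    D0 = 2.0e-3                                  # nm^2/ps
    dt = 1.0
    n_frames, n_part = 2000, 120
    steps = rng.normal(scale=np.sqrt(2 * D0 * dt), size=(n_frames, n_part, 3))
    pts = np.cumsum(steps, axis=0) + 10.0
    traj = _point_trajectory(pts, np.array([1e3, 1e3, 1e3]))
    d = obs.diffusion_coefficient(traj, fit_window_ps=200.0,
                                  effective_time_factor=1.0, species="P4")
    assert d["D_cg"] == pytest.approx(D0 * units.CM2_S_PER_NM2_PS, rel=0.05)
    # the x4 effective-time convention divides the slope accordingly
    d4 = obs.diffusion_coefficient(traj, fit_window_ps=200.0,
                                   effective_time_factor=4.0, species="P4")
    assert d4["D_cg"] == pytest.approx(d["D_cg"] / 4.0, rel=1e-9)
    assert d4["D_molecular"] == pytest.approx(d["D_cg"], rel=1e-9)


def test_diffusion_window_error(short_nvt):
    _, traj, _ = short_nvt
    with pytest.raises(ValueError):
        obs.diffusion_coefficient(traj, fit_window_ps=1e6)


# ---------------------------------------------------------------------------
# potential profile
# ---------------------------------------------------------------------------

def test_potential_zero_for_neutral():
    box = np.array([4.0, 4.0, 6.0])
    pts = np.tile(np.array([[1.0, 1, 1], [2.0, 2, 2]]), (5, 1, 1))
    traj = _point_trajectory(pts, box)
    z, rho, phi = obs.potential_profile(traj, bin_width=0.2)
    assert np.allclose(rho, 0.0)
    assert np.allclose(phi, 0.0)


def test_potential_parallel_plates():
    """Two opposite charge sheets give a linear ramp between them."""
    from polwater.topology import System, single_bead
    box = np.array([3.0, 3.0, 9.0])
    nq = 64
    rngl = np.random.default_rng(3)
    z1, z2 = 3.0, 6.0
    pos, charges = [], []
    system = System(box)
    for z0, qv in ((z1, 1.0 / nq), (z2, -1.0 / nq)):
        for _ in range(nq):
            x, y = rngl.uniform(0, 3.0, size=2)
            system.add_molecule(single_bead("DUM", charge=qv),
                                np.array([[x, y, z0]]))
            pos.append([x, y, z0])
    pts = np.asarray(pos)[None, :, :]
    traj = Trajectory(np.array([1.0]), pts, box[None, :], system=system)
    z, rho, phi = obs.potential_profile(traj, bin_width=0.15)
    inner = (z > z1 + 0.5) & (z < z2 - 0.5)
    outer_hi = z > z2 + 0.5
    # linear between the plates: second differences vanish
    slope = np.gradient(phi, z)
    assert np.std(slope[inner]) < 0.02 * np.abs(slope[inner].mean())
    # constant outside
    assert np.ptp(phi[outer_hi]) < 1e-6 * max(1.0, np.ptp(phi))
    # magnitude matches the parallel-plate closed form E = sigma/eps0
    sigma_s = 1.0 / (3.0 * 3.0)
    e_expected = sigma_s / units.EPS0 / units.FIELD_CONV   # V/nm
    assert abs(slope[inner].mean()) == pytest.approx(e_expected, rel=0.05)


def test_potential_axis_validation(short_nvt):
    _, traj, _ = short_nvt
    with pytest.raises(ValueError):
        obs.potential_profile(traj, axis="w")


# ---------------------------------------------------------------------------
# unit round-trips
# ---------------------------------------------------------------------------

def test_unit_constants_consistency():
    assert units.DEBYE_PER_E_NM == pytest.approx(48.0321, abs=1e-4)
    # 1 bar nm = 0.1 mN/m
    assert 1.0 * units.MN_PER_M_PER_BAR_NM == pytest.approx(0.1)
    # amu/nm^3 <-> kg/m^3 round trip
    assert units.kg_m3_to_amu_per_nm3(
        units.amu_per_nm3_to_kg_m3(5.0)) == pytest.approx(5.0, rel=1e-12)
    # eps0 consistent with the electric conversion factor
    assert units.EPS0 == pytest.approx(1.0 / (4 * np.pi * units.F_ELEC))


def test_block_average_error_scaling(rng):
    x = rng.normal(size=10000)
    m, e = obs.block_average(x, n_blocks=10)
    assert abs(m) < 0.05
    assert 0.2 / np.sqrt(10000) < e < 5.0 / np.sqrt(10000)
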