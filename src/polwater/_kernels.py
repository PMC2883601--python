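"""Numba-compiled inner loops: neighbour search, nonbonded/bonded forces,
soft-core coupled pairs, and the iterative constraint solver.

All kernels work in the md unit system (nm, ps, amu, e, kJ/mol) on plain
float64/int64 arrays.  Shift-polynomial coefficients are precomputed in
:mod:`polwater.forcefield` and passed in as scalars.
"""

import numpy as np
from numba import njit

_OPTS = dict(cache=True, fastmath=True)


@njit(**_OPTS)
def build_pairs(pos, box, rlist2, has_lj, charges, type_idx, c12_tab,
                c6_tab, coul_pref, excl_ptr, excl_idx, solute_mask,
                lj_ij, lj_c12, lj_c6, q_ij, q_qq, cpl_ij):
    """Verlet lists with per-pair precomputed parameters (single pass).

    A pair enters when it is not excluded and at least one interaction
    exists; LJ-bearing pairs go into lj_* (c12/c6 table values), charged
    pairs into q_* (prefactored charge product) — a pair with both
    interactions appears in both lists.  Pairs with exactly one site in
    the solute mask go into cpl_ij for the soft-core path instead.
    Returns (n_lj, n_q, n_coupled); n_lj = -1 signals insufficient
    capacity.
    """
    n = pos.shape[0]
    cap_lj = lj_ij.shape[0]
    cap_q = q_ij.shape[0]
    ccap = cpl_ij.shape[0]
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    a = 0
    b = 0
    c = 0
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        lj_i = has_lj[i]
        qi = charges[i]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= box[0] * np.rint(dx * ibx)
            dy -= box[1] * np.rint(dy * iby)
            dz -= box[2] * np.rint(dz * ibz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rlist2:
                continue
            lj = lj_i and has_lj[j]
            qq = qi * charges[j]
            if not (lj or qq != 0.0):
                continue
            excluded = False
            for k in range(excl_ptr[i], excl_ptr[i + 1]):
                if excl_idx[k] == j:
                    excluded = True
                    break
            if excluded:
                continue
            if solute_mask[i] != solute_mask[j]:
                if c >= ccap:
                    return -1, -1, -1
                cpl_ij[c, 0] = i
                cpl_ij[c, 1] = j
                c += 1
                continue
            if lj:
                if a >= cap_lj:
                    return -1, -1, -1
                lj_ij[a, 0] = i
                lj_ij[a, 1] = j
                ti = type_idx[i]
                tj = type_idx[j]
                lj_c12[a] = c12_tab[ti, tj]
                lj_c6[a] = c6_tab[ti, tj]
                a += 1
            if qq != 0.0:
                if b >= cap_q:
                    return -1, -1, -1
                q_ij[b, 0] = i
                q_ij[b, 1] = j
                q_qq[b] = coul_pref * qq
                b += 1
    return a, b, c


@njit(inline="always")
def _phi_f_12_6(r, rs, rc, A12, B12, C12, A6, B6, C6):
    """Shifted 1/r^12 and 1/r^6 potential/force factors (r < rc assumed)."""
    inv = 1.0 / r
    inv2 = inv * inv
    inv6 = inv2 * inv2 * inv2
    inv12 = inv6 * inv6
    if r >= rs:
        dr = r - rs
        dr2 = dr * dr
        dr3 = dr2 * dr
        dr4 = dr3 * dr
        phi12 = inv12 - A12 / 3.0 * dr3 - B12 / 4.0 * dr4 - C12
        f12 = 12.0 * inv12 * inv + A12 * dr2 + B12 * dr3
        phi6 = inv6 - A6 / 3.0 * dr3 - B6 / 4.0 * dr4 - C6
        f6 = 6.0 * inv6 * inv + A6 * dr2 + B6 * dr3
    else:
        phi12 = inv12 - C12
        f12 = 12.0 * inv12 * inv
        phi6 = inv6 - C6
        f6 = 6.0 * inv6 * inv
    return phi12, f12, phi6, f6


@njit(inline="always")
def _phi_f_1(r, rc, A1, B1, C1):
    inv = 1.0 / r
    phi1 = inv - A1 / 3.0 * r ** 3 - B1 / 4.0 * r ** 4 - C1
    f1 = inv * inv + A1 * r * r + B1 * r ** 3
    return phi1, f1


@njit(**_OPTS)
def lj_pair_forces(pos, box, n_pairs, pair_ij, pair_c12, pair_c6,
                   rs, rc, A12, B12, C12, A6, B6, C6, forces, virial):
    """Shifted LJ over the LJ pair list; accumulates forces/upper virial.

    Returns (E_lj, error_pair_index); error >= 0 flags a pair closer
    than 1e-5 nm.
    """
    e_lj = 0.0
    err = -1
    rc2 = rc * rc
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    for p in range(n_pairs):
        i = pair_ij[p, 0]
        j = pair_ij[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx * ibx)
        dy -= box[1] * np.rint(dy * iby)
        dz -= box[2] * np.rint(dz * ibz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < 1e-10:
            err = p
            continue
        r = np.sqrt(r2)
        inv = 1.0 / r
        c12 = pair_c12[p]
        c6 = pair_c6[p]
        inv2 = inv * inv
        inv6 = inv2 * inv2 * inv2
        inv12 = inv6 * inv6
        if r >= rs:
            dr = r - rs
            dr2 = dr * dr
            dr3 = dr2 * dr
            dr4 = dr3 * dr
            e_lj += (c12 * (inv12 - A12 / 3.0 * dr3 - B12 / 4.0 * dr4 - C12)
                     - c6 * (inv6 - A6 / 3.0 * dr3 - B6 / 4.0 * dr4 - C6))
            fs = (c12 * (12.0 * inv12 * inv + A12 * dr2 + B12 * dr3)
                  - c6 * (6.0 * inv6 * inv + A6 * dr2 + B6 * dr3))
        else:
            e_lj += c12 * (inv12 - C12) - c6 * (inv6 - C6)
            fs = 12.0 * c12 * inv12 * inv - 6.0 * c6 * inv6 * inv
        g = fs * inv
        fx = g * dx
        fy = g * dy
        fz = g * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[1, 1] += dy * fy
        virial[2, 2] += dz * fz
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 2] += dy * fz
    return e_lj, err


@njit(**_OPTS)
def coulomb_pair_forces(pos, box, n_pairs, pair_ij, pair_qq,
                        rc, A1, B1, C1, forces, virial):
    """Shifted Coulomb over the charged pair list (upper-triangle virial).

    Returns (E_coul, error_pair_index).
    """
    e_coul = 0.0
    err = -1
    rc2 = rc * rc
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    A1_3 = A1 / 3.0
    B1_4 = B1 / 4.0
    for p in range(n_pairs):
        i = pair_ij[p, 0]
        j = pair_ij[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx * ibx)
        dy -= box[1] * np.rint(dy * iby)
        dz -= box[2] * np.rint(dz * ibz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < 1e-10:
            err = p
            continue
        r = np.sqrt(r2)
        inv = 1.0 / r
        qq = pair_qq[p]
        e_coul += qq * (inv - A1_3 * r2 * r - B1_4 * r2 * r2 - C1)
        fs = qq * (inv * inv + A1 * r2 + B1 * r2 * r)
        g = fs * inv
        fx = g * dx
        fy = g * dy
        fz = g * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[1, 1] += dy * fy
        virial[2, 2] += dz * fz
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 2] += dy * fz
    return e_coul, err


@njit(**_OPTS)
def softcore_forces(pos, box, pairs, type_idx, c12_tab, c6_tab, has_lj,
                    charges, coul_pref, lam, alpha_sc, sigma_tab, sigma_def,
                    rs, rc, A12, B12, C12, A6, B6, C6, A1, B1, C1,
                    forces, virial):
    """Soft-core (separation-shifted) coupled pairs at coupling lam.

    The bare shifted pair potential V(r) is evaluated at
    r_A = (r^6 + alpha sigma^6 (1-lam))^(1/6) and scaled by lam:
    H(lam) = lam V(r_A).  Returns (E_sc, dH/dlam, error index).
    lam = 1 reproduces the plain kernels exactly; lam = 0 is fully
    decoupled with finite energy everywhere.
    """
    e_sc = 0.0
    dhdl = 0.0
    err = -1
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        lj = has_lj[i] and has_lj[j]
        if lj:
            sig = sigma_tab[type_idx[i], type_idx[j]]
        else:
            sig = sigma_def
        shift6 = alpha_sc * sig ** 6 * (1.0 - lam)
        ra6 = r2 * r2 * r2 + shift6
        ra = ra6 ** (1.0 / 6.0)
        if ra >= rc:
            continue
        if ra < 1e-10:
            err = p
            continue
        # bare potential and force factor at ra
        v = 0.0
        fker = 0.0
        if lj:
            c12 = c12_tab[type_idx[i], type_idx[j]]
            c6 = c6_tab[type_idx[i], type_idx[j]]
            phi12, f12, phi6, f6 = _phi_f_12_6(ra, rs, rc, A12, B12, C12,
                                               A6, B6, C6)
            v += c12 * phi12 - c6 * phi6
            fker += c12 * f12 - c6 * f6
        qq = charges[i] * charges[j]
        if qq != 0.0:
            phi1, f1 = _phi_f_1(ra, rc, A1, B1, C1)
            v += coul_pref * qq * phi1
            fker += coul_pref * qq * f1
        e_sc += lam * v
        # dH/dlam = V(ra) + lam * F(ra) * alpha sigma^6 / (6 ra^5)
        ra5 = ra ** 5
        dhdl += v + lam * fker * alpha_sc * sig ** 6 / (6.0 * ra5)
        # force on particles: -d(lam V(ra))/dr = lam F(ra) (r/ra)^5
        if r > 1e-12:
            fs = lam * fker * (r2 * r2 * r / ra5)
            fx = fs * dx / r
            fy = fs * dy / r
            fz = fs * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0, 0] += dx * fx
            virial[1, 1] += dy * fy
            virial[2, 2] += dz * fz
            virial[0, 1] += dx * fy
            virial[0, 2] += dx * fz
            virial[1, 0] += dy * fx
            virial[1, 2] += dy * fz
            virial[2, 0] += dz * fx
            virial[2, 1] += dz * fy
    return e_sc, dhdl, err


@njit(**_OPTS)
def bond_forces(pos, bonds, params, forces, virial):
    """Harmonic bonds E = 1/2 k (r - b0)^2 (no minimum image: molecules whole)."""
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        b0 = params[b, 0]
        kb = params[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        e += 0.5 * kb * (r - b0) ** 2
        fs = -kb * (r - b0)          # along +r_ij on i
        fx = fs * dx / r
        fy = fs * dy / r
        fz = fs * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[1, 1] += dy * fy
        virial[2, 2] += dz * fz
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
    return e


@njit(**_OPTS)
def angle_forces(pos, angles, params, forces, virial):
    """Angle potentials, central atom second in each triplet.

    Two functional forms, chosen per angle by params[:, 2]:
    0 - harmonic in the angle, E = 1/2 K (theta - theta0)^2.  Its
        1/sin(theta) force factor is regularised: below 1e-4 rad the
        force is taken in its (vanishing) small-angle limit, and
        sin(theta) is floored at 1e-6 elsewhere.
    1 - cosine-harmonic, E = 1/2 K (cos theta - cos theta0)^2, the
        form this force-field family uses for its bonded angles; it is
        singularity-free and much softer around theta0 = 0.
    """
    e = 0.0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        th0 = params[a, 0]
        ka = params[a, 1]
        cosine_form = params[a, 2] != 0.0
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        if cosine_form:
            dc = c - np.cos(th0)
            e += 0.5 * ka * dc * dc
            # F_i = -dE/dc * dc/dr_i = -K dc (v_hat - c u_hat)/nu
            coef = -ka * dc
        else:
            theta = np.arccos(c)
            dth = theta - th0
            e += 0.5 * ka * dth * dth
            if theta < 1e-4 and th0 == 0.0:
                continue              # force -> 0 in the small-angle limit
            s = np.sqrt(1.0 - c * c)
            if s < 1e-6:
                s = 1e-6
            coef = ka * dth / s
        # dtheta/dr_i = -(v_hat - c u_hat)/(nu s); F_i = -dE/dth * dth/dr_i
        #             = +K dth (v_hat - c u_hat)/(nu s)
        fix = coef * (vx / nv - c * ux / nu) / nu
        fiy = coef * (vy / nv - c * uy / nu) / nu
        fiz = coef * (vz / nv - c * uz / nu) / nu
        fkx = coef * (ux / nu - c * vx / nv) / nv
        fky = coef * (uy / nu - c * vy / nv) / nv
        fkz = coef * (uz / nu - c * vz / nv) / nv
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        virial[0, 0] += ux * fix + vx * fkx
        virial[1, 1] += uy * fiy + vy * fky
        virial[2, 2] += uz * fiz + vz * fkz
        virial[0, 1] += ux * fiy + vx * fky
        virial[0, 2] += ux * fiz + vx * fkz
        virial[1, 0] += uy * fix + vy * fkx
        virial[1, 2] += uy * fiz + vy * fkz
        virial[2, 0] += uz * fix + vz * fkx
        virial[2, 1] += uz * fiy + vz * fky
    return e


@njit(**_OPTS)
def shake(pos_ref, pos_new, cons, lengths, invmass, tol, maxiter):
    """Iterative pair-wise constraint solver (SHAKE-style).

    Corrects pos_new in place so every constrained distance equals its
    target within tol, displacing partners along the reference bond
    direction with inverse-mass weighting.  Returns (iterations used,
    per-constraint accumulated multiplier g); iterations == -1 flags
    non-convergence.  The constraint force on site i over the step is
    -g * s_ij / dt^2 with s_ij the reference bond vector.
    """
    nc = cons.shape[0]
    gsum = np.zeros(nc)
    if nc == 0:
        return 0, gsum
    for it in range(maxiter):
        done = True
        for c in range(nc):
            i = cons[c, 0]
            j = cons[c, 1]
            L = lengths[c]
            dx = pos_new[i, 0] - pos_new[j, 0]
            dy = pos_new[i, 1] - pos_new[j, 1]
            dz = pos_new[i, 2] - pos_new[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            d = np.sqrt(d2)
            if abs(d - L) <= tol:
                continue
            done = False
            sx = pos_ref[i, 0] - pos_ref[j, 0]
            sy = pos_ref[i, 1] - pos_ref[j, 1]
            sz = pos_ref[i, 2] - pos_ref[j, 2]
            dot = dx * sx + dy * sy + dz * sz
            if abs(dot) < 1e-12:
                dot = 1e-12
            g = (d2 - L * L) / (2.0 * (invmass[i] + invmass[j]) * dot)
            gsum[c] += g
            pos_new[i, 0] -= g * invmass[i] * sx
            pos_new[i, 1] -= g * invmass[i] * sy
            pos_new[i, 2] -= g * invmass[i] * sz
            pos_new[j, 0] += g * invmass[j] * sx
            pos_new[j, 1] += g * invmass[j] * sy
            pos_new[j, 2] += g * invmass[j] * sz
        if done:
            return it + 1, gsum
    return -1, gsum


@njit(**_OPTS)
def shake_step(pos_ref, pos_new, vel, cons, lengths, invmass, tol,
               maxiter, dt, virial):
    """SHAKE plus leapfrog bookkeeping for one MD step.

    Corrects pos_new, folds the position corrections into the half-step
    velocities (v += dx/dt), and accumulates the constraint-force virial
    -(g/dt^2) s (x) s into the 3x3 virial.  Returns the iteration count
    (-1 on non-convergence).
    """
    nc = cons.shape[0]
    if nc == 0:
        return 0
    niter, gsum = shake(pos_ref, pos_new, cons, lengths, invmass, tol,
                        maxiter)
    if niter < 0:
        return -1
    idt = 1.0 / dt
    idt2 = idt * idt
    for c in range(nc):
        i = cons[c, 0]
        j = cons[c, 1]
        g = gsum[c]
        if g == 0.0:
            continue
        sx = pos_ref[i, 0] - pos_ref[j, 0]
        sy = pos_ref[i, 1] - pos_ref[j, 1]
        sz = pos_ref[i, 2] - pos_ref[j, 2]
        # velocity correction matching the applied position corrections
        vel[i, 0] -= g * invmass[i] * sx * idt
        vel[i, 1] -= g * invmass[i] * sy * idt
        vel[i, 2] -= g * invmass[i] * sz * idt
        vel[j, 0] += g * invmass[j] * sx * idt
        vel[j, 1] += g * invmass[j] * sy * idt
        vel[j, 2] += g * invmass[j] * sz * idt
        w = -g * idt2
        virial[0, 0] += w * sx * sx
        virial[1, 1] += w * sy * sy
        virial[2, 2] += w * sz * sz
        virial[0, 1] += w * sx * sy
        virial[0, 2] += w * sx * sz
        virial[1, 2] += w * sy * sz
        virial[1, 0] += w * sy * sx
        virial[2, 0] += w * sz * sx
        virial[2, 1] += w * sz * sy
    return niter


@njit(**_OPTS)
def leapfrog(pos, vel, forces, invmass, dt, lam_T, pos_new, vel_new):
    """vel_new = lam_T (vel + f m^-1 dt); pos_new = pos + vel_new dt."""
    n = pos.shape[0]
    for i in range(n):
        im = invmass[i] * dt
        vx = lam_T * (vel[i, 0] + forces[i, 0] * im)
        vy = lam_T * (vel[i, 1] + forces[i, 1] * im)
        vz = lam_T * (vel[i, 2] + forces[i, 2] * im)
        vel_new[i, 0] = vx
        vel_new[i, 1] = vy
        vel_new[i, 2] = vz
        pos_new[i, 0] = pos[i, 0] + vx * dt
        pos_new[i, 1] = pos[i, 1] + vy * dt
        pos_new[i, 2] = pos[i, 2] + vz * dt


@njit(**_OPTS)
def kinetic_and_com(vel, masses, total_mass, remove_com, kin):
    """COM-motion removal (optional) and kinetic-energy tensor (3x3)."""
    n = vel.shape[0]
    if remove_com:
        px = 0.0
        py = 0.0
        pz = 0.0
        for i in range(n):
            m = masses[i]
            px += m * vel[i, 0]
            py += m * vel[i, 1]
            pz += m * vel[i, 2]
        vx = px / total_mass
        vy = py / total_mass
        vz = pz / total_mass
        for i in range(n):
            vel[i, 0] -= vx
            vel[i, 1] -= vy
            vel[i, 2] -= vz
    kxx = kyy = kzz = kxy = kxz = kyz = 0.0
    for i in range(n):
        m = masses[i]
        kxx += m * vel[i, 0] * vel[i, 0]
        kyy += m * vel[i, 1] * vel[i, 1]
        kzz += m * vel[i, 2] * vel[i, 2]
        kxy += m * vel[i, 0] * vel[i, 1]
        kxz += m * vel[i, 0] * vel[i, 2]
        kyz += m * vel[i, 1] * vel[i, 2]
    kin[0, 0] = kxx
    kin[1, 1] = kyy
    kin[2, 2] = kzz
    kin[0, 1] = kin[1, 0] = kxy
    kin[0, 2] = kin[2, 0] = kxz
    kin[1, 2] = kin[2, 1] = kyz
    return 0.5 * (kxx + kyy + kzz)


@njit(**_OPTS)
def max_displacement2(pos, pos_ref):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - pos_ref[i, 0]
        dy = pos[i, 1] - pos_ref[i, 1]
        dz = pos[i, 2] - pos_ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return m
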