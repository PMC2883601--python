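"""Seeded, reproducible construction of simulation systems.

Builders place molecules on jittered FCC-like lattices (no LJ-centre
pair closer than a minimum separation), orient the water satellites with
zero initial dipole, and draw Maxwell-Boltzmann velocities, all from a
single integer seed so that identical arguments give bit-identical
systems.
"""

from __future__ import annotations

import numpy as np

from . import units
from .forcefield import ForceField
from .topology import (MoleculeTopology, System, WATER_BOND_LENGTH, alkane,
                       ion, polarizable_water, standard_water)

__all__ = [
    "PackingError",
    "CompositionError",
    "build_water_box",
    "build_slab_system",
    "insert_ions",
    "assign_velocities",
    "kinetic_temperature",
]

#: minimum LJ-centre separation accepted when packing (nm)
MIN_SEPARATION = 0.4

#: rough liquid alkane mass density used to size alkane slabs (kg/m^3)
ALKANE_DENSITY = 750.0

WATER_MASS = 72.0


class PackingError(ValueError):
    """Requested density/counts cannot be packed without overlaps."""


class CompositionError(ValueError):
    """Requested composition is inconsistent (e.g. too many ions)."""


# ---------------------------------------------------------------------------
# lattice helpers
# ---------------------------------------------------------------------------

def _fcc_slots(origin, extent, n, rng, min_sep=MIN_SEPARATION):
    """n jittered FCC lattice points inside an orthorhombic region."""
    origin = np.asarray(origin, float)
    extent = np.asarray(extent, float)
    if n < 1:
        return np.zeros((0, 3))
    vol = float(np.prod(extent))
    a = (4.0 * vol / n) ** (1.0 / 3.0)     # target cubic cell edge
    nc = np.maximum(1, np.round(extent / a).astype(int))
    while 4 * np.prod(nc) < n:
        # grow the dimension whose cell is currently largest
        nc[np.argmax(extent / nc)] += 1
    cell = extent / nc
    # nearest-neighbour distance on an FCC lattice with unequal cell edges
    nn = 0.5 * min(
        np.hypot(cell[0], cell[1]),
        np.hypot(cell[0], cell[2]),
        np.hypot(cell[1], cell[2]),
    )
    if nn <= min_sep:
        raise PackingError(
            f"cannot place {n} sites in volume {vol:.2f} nm^3 with "
            f"minimum separation {min_sep} nm (lattice spacing {nn:.3f} nm)")
    jitter = min(0.05, 0.45 * (nn - min_sep))
    base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    ix, iy, iz = np.meshgrid(*(np.arange(k) for k in nc), indexing="ij")
    corners = np.stack([ix, iy, iz], axis=-1).reshape(-1, 1, 3)
    slots = ((corners + base) * cell).reshape(-1, 3) + origin
    order = rng.permutation(len(slots))[:n]
    pts = slots[order]
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts


def _add_water(system, centers, model, rng, q=0.46,
               angle_k=None, angle_form=1):
    """Add water molecules at the given centres.

    Polarizable satellites start coincident at distance l from the
    centre along a random direction, i.e. at the theta0 = 0 equilibrium
    with zero molecular dipole.
    """
    if model == "polarizable":
        from .topology import WATER_ANGLE_K
        topo = polarizable_water(q, WATER_ANGLE_K if angle_k is None
                                 else angle_k, angle_form)
        for c in centers:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            sat = c + WATER_BOND_LENGTH * u
            system.add_molecule(topo, np.array([c, sat, sat]))
    elif model == "standard":
        topo = standard_water()
        for c in centers:
            system.add_molecule(topo, c.reshape(1, 3))
    else:
        raise ValueError(f"unknown water model {model!r}")


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------

def n_dof(system: System) -> int:
    """Kinetic degrees of freedom: 3N - N_constraints - 3 (COM removed)."""
    return 3 * system.n_sites - len(system.constraints) - 3


def kinetic_temperature(system: System) -> float:
    ke = 0.5 * float(np.sum(system.masses[:, None] * system.velocities ** 2))
    dof = max(n_dof(system), 1)
    return 2.0 * ke / (dof * units.KB)


def assign_velocities(system: System, temperature: float, rng) -> None:
    """Maxwell-Boltzmann draw, COM removal, exact rescale to temperature."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sigma = np.sqrt(units.KB * temperature / system.masses)
    v = rng.normal(size=(system.n_sites, 3)) * sigma[:, None]
    p = system.masses @ v
    v -= p / system.total_mass
    system.velocities = v
    t_now = kinetic_temperature(system)
    if t_now > 0:
        system.velocities *= np.sqrt(temperature / t_now)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_water_box(n_beads: int, initial_density: float = 1000.0,
                    model: str = "polarizable", seed: int = 0,
                    temperature: float = 300.0, q: float = 0.46,
                    angle_k: float | None = None,
                    angle_form: int = 1) -> System:
    """Cubic bulk water box at a requested initial mass density (kg/m^3).

    q and angle_k expose the satellite charge and angle force constant
    for parameterisation-scan runs; the defaults are the production
    parameters.
    """
    if n_beads < 1:
        raise ValueError("need at least one water bead")
    if initial_density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    rho_amu = units.kg_m3_to_amu_per_nm3(initial_density)
    volume = n_beads * WATER_MASS / rho_amu
    edge = volume ** (1.0 / 3.0)
    box = np.full(3, edge)
    system = System(box)
    centers = _fcc_slots(np.zeros(3), box, n_beads, rng)
    _add_water(system, centers, model, rng, q, angle_k, angle_form)
    assign_velocities(system, temperature, rng)
    system.metadata.update(model=model, kind="bulk", seed=seed,
                           temperature=temperature,
                           initial_density=initial_density)
    return system


def build_slab_system(composition: str, counts: dict, box_xy: float = 6.0,
                      model: str = "polarizable", seed: int = 0,
                      temperature: float = 300.0) -> System:
    """Slab geometry in the XY plane: water/vacuum or water/alkane.

    composition: 'water/vacuum', 'water/hexadecane' or 'water/octane'.
    counts: per-species molecule counts, e.g. {'water': 450, 'octane': 182}.
    Alkanes are linear C1 chains (hexadecane 4 beads, octane 2, butane 1)
    stacked as a slab; the water occupies the adjacent z-region, and for
    water/vacuum an empty region at least as thick as the water slab (and
    >= 3 nm) is left.
    """
    species = composition.split("/")
    if species[0] != "water" or len(species) != 2:
        raise ValueError(f"unknown composition {composition!r}")
    other = species[1]
    n_water = int(counts.get("water", 0))
    n_other = int(counts.get(other, 0)) if other != "vacuum" else 0
    if n_water <= 0 and n_other <= 0:
        raise CompositionError("need a positive count for at least one species")

    rng = np.random.default_rng(seed)
    area = box_xy * box_xy
    rho_w = units.kg_m3_to_amu_per_nm3(1000.0)
    t_water = n_water * WATER_MASS / (rho_w * area) if n_water else 0.0

    alkane_beads = {"hexadecane": 4, "octane": 2, "butane": 1}
    if other == "vacuum":
        t_other = max(t_water, 3.0)
        chain_len = 0
    else:
        try:
            chain_len = alkane_beads[other]
        except KeyError:
            raise ValueError(f"unknown slab partner {other!r}") from None
        rho_a = units.kg_m3_to_amu_per_nm3(ALKANE_DENSITY)
        t_other = n_other * chain_len * 72.0 / (rho_a * area)
        # a too-thin slab cannot hold the chain lattice at safe spacing;
        # grow it if needed (pressure coupling relaxes it later)
        if n_other > 0:
            grid = _alkane_grid(n_other, box_xy, box_xy, chain_len)
            t_other = max(t_other, grid[2] * 0.47 + 2 * 0.18)

    box = np.array([box_xy, box_xy, t_other + t_water])
    system = System(box)

    # inset each lattice region at the interfaces so no cross-species
    # pair starts inside the repulsive core
    gap = 0.18
    if other != "vacuum" and n_other > 0:
        _add_alkane_slab(system, other, chain_len, n_other,
                         z0=gap, z1=t_other - gap, rng=rng)
    if n_water > 0:
        centers = _fcc_slots([0, 0, t_other + gap],
                             [box_xy, box_xy, t_water - 2 * gap],
                             n_water, rng)
        _add_water(system, centers, model, rng)

    assign_velocities(system, temperature, rng)
    system.metadata.update(model=model, kind="slab", composition=composition,
                           seed=seed, temperature=temperature,
                           slab_axis="z", slab_z=(t_other, t_other + t_water))
    return system


def _alkane_grid(n_mol, box_x, box_y, chain_len):
    """Chain-lattice grid (per_row, ny, nz) with safe row spacing."""
    chain_span = (chain_len - 1) * 0.47
    per_row = max(1, int(box_x // (chain_span + 0.52)))
    n_rows = -(-n_mol // per_row)
    ny = max(1, int(box_y // 0.45))
    nz = -(-n_rows // ny)
    # rebalance toward square cells where possible
    while ny > 1 and -(-n_rows // (ny - 1)) == nz:
        ny -= 1
    return per_row, ny, nz


def _add_alkane_slab(system, name, chain_len, n_mol, z0, z1, rng):
    """Stack linear alkane chains (along x) into the region z0..z1."""
    box_x, box_y = system.box[0], system.box[1]
    topo = alkane(chain_len, name=name.upper()[:3])
    per_row, ny, nz = _alkane_grid(n_mol, box_x, box_y, chain_len)
    thickness = z1 - z0
    dy, dz = box_y / ny, thickness / nz
    if min(dy, dz) < 0.4:
        raise PackingError(
            f"cannot stack {n_mol} {name} chains into the slab region "
            f"(row spacing {min(dy, dz):.2f} nm)")
    placed = 0
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(per_row):
                if placed >= n_mol:
                    return
                x0 = (box_x / per_row) * ix + 0.2
                y = (iy + 0.5) * dy
                z = z0 + (iz + 0.5) * dz
                jit = rng.uniform(-0.03, 0.03, size=(chain_len, 3))
                pos = np.array([[x0 + 0.47 * k, y, z]
                                for k in range(chain_len)]) + jit
                system.add_molecule(topo, pos)
                placed += 1
    if placed < n_mol:
        raise PackingError(f"placed only {placed}/{n_mol} {name} chains")


def insert_ions(system: System, n_cation: int, n_anion: int,
                seed: int = 0) -> System:
    """Replace randomly chosen water beads by single-site Qd(+1)/Qa(-1) ions."""
    if n_cation == 0 and n_anion == 0:
        return system
    rng = np.random.default_rng(seed)
    water_ids = [m for m, (topo, _) in enumerate(system.molecules)
                 if topo.name in ("PW", "W4")]
    n_replace = n_cation + n_anion
    if n_replace > len(water_ids):
        raise CompositionError(
            f"cannot replace {n_replace} waters, only {len(water_ids)} present")
    chosen = rng.permutation(water_ids)[:n_replace]
    kinds = {mid: ("NA" if k < n_cation else "CL")
             for k, mid in enumerate(chosen)}

    new = System(system.box)
    for mol_id, (topo, off) in enumerate(system.molecules):
        sites = system.molecule_sites(mol_id)
        if mol_id in kinds:
            itopo = ion(kinds[mol_id])
            pos = system.positions[sites[0]].reshape(1, 3)
            new_id = new.add_molecule(itopo, pos)
            # carry over the molecular COM velocity (equal 72 amu mass)
            msum = system.masses[sites].sum()
            vcom = (system.masses[sites] @ system.velocities[sites]) / msum
            new.velocities[new.molecule_sites(new_id)] = vcom
        else:
            new_id = new.add_molecule(topo, system.positions[sites])
            new.velocities[new.molecule_sites(new_id)] = \
                system.velocities[sites]
    new.metadata = dict(system.metadata)
    new.metadata.update(n_cation=n_cation, n_anion=n_anion)
    return new
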