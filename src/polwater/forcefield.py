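"""Nonbonded parameter database and shifted pair-interaction kernels.

The force field is coarse-grained at a 4:1 mapping: each bead stands for
roughly four heavy atoms, and a water bead (72 amu) for four water
molecules.  Polarizable water is a three-site bead: a neutral
Lennard-Jones centre ``W`` with two charged satellites ``WP``/``WM``
(+q/-q, q = 0.46 e) constrained at l = 0.14 nm, so the bead carries an
orientational dipole between 0 and 2ql.  Explicit charges are screened by
a uniform relative dielectric constant eps_r = 2.5 (the standard,
non-polarizable variant uses eps_r = 15).

Pair interactions follow the conventional recipe of this force-field
family: LJ 12-6 with the well depth set by a discrete interaction level
(O..IX), and Coulomb between charged sites, both smoothly shifted so that
potential and force vanish at the 1.2 nm cutoff (LJ shifted from 0.9 nm,
Coulomb shifted over the whole range).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "BeadType",
    "LJParams",
    "ForceField",
    "ParameterLookupError",
    "NoLJError",
    "lj_shifted",
    "coulomb_shifted",
    "shift_coefficients",
    "R_CUT",
    "R_SHIFT_LJ",
]

# Canonical cutoffs (nm)
R_CUT = 1.2
R_SHIFT_LJ = 0.9

#: 95% cross-interaction scaling of the polarizable-water LJ well depth
#: against non-charged types, relative to the P4 row.
POL_CROSS_SCALE = 0.95


class ParameterLookupError(KeyError):
    """Raised when a bead type or type pair is not in the database."""


class NoLJError(ParameterLookupError):
    """Raised when an LJ lookup involves a site with no LJ interaction."""


@dataclass(frozen=True)
class BeadType:
    name: str
    mass: float          # amu
    charge: float        # default site charge, e
    has_lj: bool
    has_coulomb: bool


@dataclass(frozen=True)
class LJParams:
    epsilon: float       # kJ/mol
    sigma: float         # nm

    @property
    def c12(self) -> float:
        return 4.0 * self.epsilon * self.sigma ** 12

    @property
    def c6(self) -> float:
        return 4.0 * self.epsilon * self.sigma ** 6


def _load_database() -> dict:
    with importlib.resources.files("polwater.data").joinpath(
        "interactions.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


_DB = _load_database()

_PNC_TYPES = ("P5", "P4", "P3", "P2", "P1", "Nda", "Nd", "Na", "N0",
              "C5", "C4", "C3", "C2", "C1")


class ForceField:
    """Interaction matrix for one force-field variant.

    Variants:

    ``polarizable``
        Three-site water with the revised charged-type rows, eps_r = 2.5.
        ``polarizable-92`` / ``polarizable-100`` change only the
        water cross-interaction scaling (0.92 / 1.0) used for
        solvation-free-energy comparisons.
    ``standard``
        Single-site P4 water, original charged-type rows, eps_r = 15.
    ``early``
        As ``standard`` but with the Q-C1/C2 interactions at level VIII,
        the choice of the first force-field generation.
    """

    VARIANTS = ("polarizable", "polarizable-92", "polarizable-100",
                "standard", "early")

    def __init__(self, variant: str = "polarizable"):
        if variant not in self.VARIANTS:
            raise ValueError(
                f"unknown force-field variant {variant!r}; "
                f"choose from {self.VARIANTS}")
        self.variant = variant
        self.polarizable = variant.startswith("polarizable")
        self.eps_r = 2.5 if self.polarizable else 15.0
        if variant == "polarizable-92":
            self.pol_cross_scale = 0.92
        elif variant == "polarizable-100":
            self.pol_cross_scale = 1.00
        else:
            self.pol_cross_scale = POL_CROSS_SCALE

        self._types = {
            name: BeadType(name, d["mass"], float(d["charge"]),
                           bool(d["lj"]), bool(d["coulomb"]))
            for name, d in _DB["bead_types"].items()
        }
        self._level_eps = {k: float(v) for k, v in _DB["levels"].items()}
        self._sigma_default = float(_DB["sigma_default"])
        self._sigma_by_level = {k: float(v)
                                for k, v in _DB["sigma_by_level"].items()}
        self._levels = self._assemble_levels(variant)

    # -- database assembly -------------------------------------------------

    def _assemble_levels(self, variant: str) -> dict:
        levels: dict[tuple, str] = {}

        def put(a, b, lev):
            levels[(a, b)] = lev
            levels[(b, a)] = lev

        for key, lev in _DB["common_pairs"].items():
            a, b = key.split(",")
            put(a, b, lev)

        block = ("polarizable_pairs" if self.polarizable
                 else "standard_pairs")
        for key, lev in _DB[block].items():
            a, b = key.split(",")
            put(a, b, lev)

        if variant == "early":
            for q in ("Qda", "Qd", "Qa", "Q0"):
                put(q, "C1", "VIII")
                put(q, "C2", "VIII")
        return levels

    # -- queries -----------------------------------------------------------

    def bead_type(self, name: str) -> BeadType:
        try:
            return self._types[name]
        except KeyError:
            raise ParameterLookupError(f"unknown bead type {name!r}") from None

    @property
    def bead_type_names(self):
        return tuple(self._types)

    def level(self, type_a: str, type_b: str) -> str:
        """Interaction level for a registered LJ pair."""
        self._check_lj(type_a)
        self._check_lj(type_b)
        try:
            return self._levels[(type_a, type_b)]
        except KeyError:
            raise ParameterLookupError(
                f"no interaction level declared for pair "
                f"({type_a}, {type_b})") from None

    def level_epsilon(self, level: str) -> float:
        return self._level_eps[level]

    def lookup_lj_params(self, type_a: str, type_b: str) -> LJParams:
        """LJ well depth and size for a type pair (symmetric).

        The polarizable water centre W takes its cross interaction with
        non-charged types from the P4 row, scaled to 95% of the well
        depth; its interactions with charged Q types and with itself use
        the revised matrix entries directly.
        """
        self._check_lj(type_a)
        self._check_lj(type_b)
        for a, b in ((type_a, type_b), (type_b, type_a)):
            if self.polarizable and a == "W" and b in _PNC_TYPES:
                lev = self._levels[("P4", b)]
                eps = self.pol_cross_scale * self._level_eps[lev]
                return LJParams(eps, self._sigma_for(lev))
        lev = self.level(type_a, type_b)
        return LJParams(self._level_eps[lev], self._sigma_for(lev))

    def _sigma_for(self, level: str) -> float:
        return self._sigma_by_level.get(level, self._sigma_default)

    def _check_lj(self, name: str):
        t = self.bead_type(name)
        if not t.has_lj:
            raise NoLJError(f"bead type {name!r} has no LJ interaction")

    @property
    def water_type(self) -> str:
        """LJ centre type of the water model in this variant."""
        return "W" if self.polarizable else "P4"


# ---------------------------------------------------------------------------
# Shifted nonbonded kernels
# ---------------------------------------------------------------------------

def shift_coefficients(alpha: int, r_shift: float, r_cut: float):
    """Polynomial shift coefficients (A, B, C) for a 1/r^alpha term.

    For r_shift <= r < r_cut the force is
    ``alpha/r^(alpha+1) + A (r-r_shift)^2 + B (r-r_shift)^3`` and the
    potential its exact antiderivative minus the constant C; both vanish
    smoothly (value and slope of the force) at r_cut.  Below r_shift the
    force is the bare power law and the potential is offset by C.
    """
    if not r_shift < r_cut:
        raise ValueError("require r_shift < r_cut")
    d = r_cut - r_shift
    g = alpha / r_cut ** (alpha + 1)
    gp = -alpha * (alpha + 1) / r_cut ** (alpha + 2)
    B = 2.0 * g / d ** 3 - gp / d ** 2
    A = -3.0 * g / d ** 2 + gp / d
    C = 1.0 / r_cut ** alpha - A / 3.0 * d ** 3 - B / 4.0 * d ** 4
    return A, B, C


def _phi_and_f(r, alpha, r_shift, r_cut):
    """Shifted potential and force factors for a 1/r^alpha term (array-safe)."""
    A, B, C = shift_coefficients(alpha, r_shift, r_cut)
    r = np.asarray(r, dtype=float)
    inside = r < r_cut
    shifted = inside & (r >= r_shift)
    core = r < r_shift
    dr = np.where(shifted, r - r_shift, 0.0)
    rsafe = np.where(r > 0, r, 1.0)
    phi = np.zeros_like(r)
    f = np.zeros_like(r)
    phi = np.where(inside,
                   1.0 / rsafe ** alpha - A / 3.0 * dr ** 3
                   - B / 4.0 * dr ** 4 - C,
                   0.0)
    f = np.where(inside, alpha / rsafe ** (alpha + 1)
                 + A * dr ** 2 + B * dr ** 3, 0.0)
    # below r_shift only the constant offset modifies the potential
    phi = np.where(core, 1.0 / rsafe ** alpha - C, phi)
    f = np.where(core, alpha / rsafe ** (alpha + 1), f)
    return phi, f


def lj_shifted(r, params: LJParams, r_shift: float = R_SHIFT_LJ,
               r_cut: float = R_CUT):
    """Shifted LJ 12-6 pair energy (kJ/mol) and scalar force (kJ/mol/nm).

    The returned force is the magnitude along r (positive = repulsive);
    force = -dE/dr everywhere, and both vanish for r >= r_cut.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ZeroDivisionError("LJ kernel is singular at r = 0")
    phi12, f12 = _phi_and_f(r, 12, r_shift, r_cut)
    phi6, f6 = _phi_and_f(r, 6, r_shift, r_cut)
    e = params.c12 * phi12 - params.c6 * phi6
    f = params.c12 * f12 - params.c6 * f6
    if e.ndim == 0:
        return float(e), float(f)
    return e, f


def coulomb_shifted(r, q_a: float, q_b: float, eps_r: float,
                    r_cut: float = R_CUT):
    """Shifted Coulomb pair energy and scalar force (shift from r = 0).

    energy = f_elec q_a q_b / (eps_r r), modified so energy and force go
    smoothly to zero at r_cut.
    """
    from .units import F_ELEC

    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ZeroDivisionError("Coulomb kernel is singular at r = 0")
    if eps_r <= 0:
        raise ValueError("eps_r must be positive")
    pref = F_ELEC * q_a * q_b / eps_r
    if pref == 0.0:
        z = np.zeros_like(r)
        return (0.0, 0.0) if z.ndim == 0 else (z, z.copy())
    phi1, f1 = _phi_and_f(r, 1, 0.0, r_cut)
    e = pref * phi1
    f = pref * f1
    if e.ndim == 0:
        return float(e), float(f)
    return e, f
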