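"""Solvation free energies and potentials of mean force.

Thermodynamic integration with soft-core decoupling of a tagged solute
(22 evenly spaced lambda windows by default, trapezoidal integration),
and umbrella-sampling recombination by the self-consistent weighted
histogram method.

Soft-core form: separation-shifted scaling.  The bare shifted pair
potential V(r) is evaluated at r_A = (r^6 + alpha sigma^6 (1-lambda))^(1/6)
and scaled linearly, H(lambda) = lambda V(r_A), with alpha = 0.5 applied
to both the LJ and Coulomb terms.  lambda = 1 recovers the plain
kernels exactly; lambda = 0 is fully decoupled and finite at r = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .engine import LambdaCoupling, Protocol, run_md
from .forcefield import (ForceField, LJParams, R_CUT, R_SHIFT_LJ,
                         coulomb_shifted, lj_shifted)
from .observables import block_average
from .topology import System

__all__ = [
    "softcore_pair",
    "TIResult",
    "ti_run",
    "ti_integrate",
    "PMFResult",
    "umbrella_pmf",
    "default_lambda_grid",
    "CoverageError",
]


class CoverageError(ValueError):
    """Umbrella windows leave a gap on the reaction coordinate."""


def default_lambda_grid(n: int = 22) -> np.ndarray:
    """Evenly spaced lambda values from 0 to 1 (22 windows by default)."""
    return np.linspace(0.0, 1.0, n)


# ---------------------------------------------------------------------------
# soft-core pair kernel (reference implementation)
# ---------------------------------------------------------------------------

def softcore_pair(r: float, lam: float, lj: LJParams | None,
                  q_a: float = 0.0, q_b: float = 0.0, eps_r: float = 2.5,
                  alpha: float = 0.5, r_cut: float = R_CUT,
                  r_shift: float = R_SHIFT_LJ):
    """Soft-core pair energy, force and dH/dlambda at separation r.

    Returns (energy kJ/mol, scalar force kJ/mol/nm along r, dH/dlambda).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    sigma = lj.sigma if lj is not None else 0.47
    shift6 = alpha * sigma ** 6 * (1.0 - lam)
    ra = (r ** 6 + shift6) ** (1.0 / 6.0)
    if ra >= r_cut:
        return 0.0, 0.0, 0.0
    v = 0.0
    fker = 0.0
    if lj is not None:
        e, f = lj_shifted(ra, lj, r_shift, r_cut)
        v += e
        fker += f
    if q_a != 0.0 and q_b != 0.0:
        e, f = coulomb_shifted(ra, q_a, q_b, eps_r, r_cut)
        v += e
        fker += f
    energy = lam * v
    force = lam * fker * (r / ra) ** 5 if r > 0 else 0.0
    dhdl = v + lam * fker * alpha * sigma ** 6 / (6.0 * ra ** 5)
    return float(energy), float(force), float(dhdl)


# ---------------------------------------------------------------------------
# thermodynamic integration
# ---------------------------------------------------------------------------

@dataclass
class TIResult:
    """Per-window <dH/dlambda> samples and the integrated free energy."""

    lambdas: np.ndarray
    dhdl_mean: np.ndarray          # kJ/mol
    dhdl_err: np.ndarray           # kJ/mol, block errors
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        lam = np.asarray(self.lambdas, float)
        if np.any(np.diff(lam) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        self.lambdas = lam
        self.dhdl_mean = np.asarray(self.dhdl_mean, float)
        self.dhdl_err = np.asarray(self.dhdl_err, float)

    @property
    def delta_g(self):
        return ti_integrate(self)


def ti_integrate(result: TIResult):
    """Trapezoidal integral of <dH/dlambda> over lambda, with propagated error.

    Decoupling integration: Delta G (solvation, negative = favourable)
    is the negative of the work of switching interactions off, i.e. the
    plain integral of dH/dlambda from the decoupled (0) to the coupled
    (1) end.
    """
    lam = result.lambdas
    if len(lam) < 2:
        raise ValueError("need at least two lambda points")
    # trapezoid weights
    w = np.zeros_like(lam)
    w[0] = (lam[1] - lam[0]) / 2.0
    w[-1] = (lam[-1] - lam[-2]) / 2.0
    if len(lam) > 2:
        w[1:-1] = (lam[2:] - lam[:-2]) / 2.0
    dg = float(w @ result.dhdl_mean)
    err = float(np.sqrt(np.sum((w * result.dhdl_err) ** 2)))
    return dg, err


def ti_run(system: System, solute_molecule: int, ff: ForceField,
           protocol: Protocol, lambdas=None, equil_fraction: float = 0.25,
           n_blocks: int = 5) -> TIResult:
    """TI over a lambda grid, decoupling one solute from its surroundings.

    Each window runs independently with its own seed (protocol.seed +
    window index); the leading equil_fraction of each window's samples
    is discarded.  Solvent-solvent interactions are untouched by lambda.
    A window whose first- and second-half means differ by more than
    three combined errors is flagged in ``warnings``.
    """
    if lambdas is None:
        lambdas = default_lambda_grid()
    lambdas = np.asarray(lambdas, float)
    means = np.zeros_like(lambdas)
    errs = np.zeros_like(lambdas)
    warnings = []
    for k, lam in enumerate(lambdas):
        wp = protocol.replace(seed=protocol.seed + 1000 * k + 1)
        coupling = LambdaCoupling(solute_molecule, float(lam))
        _, _, log = run_md(system.copy(), ff, wp, coupling=coupling)
        series = log["dHdl_kJmol"]
        n0 = int(len(series) * equil_fraction)
        series = series[n0:]
        means[k], errs[k] = block_average(series, n_blocks)
        half = len(series) // 2
        if half > 1:
            m1, e1 = block_average(series[:half], max(2, n_blocks // 2))
            m2, e2 = block_average(series[half:], max(2, n_blocks // 2))
            if abs(m1 - m2) > 3.0 * np.hypot(e1, e2) + 1e-12:
                warnings.append(
                    f"window lambda={lam:.3f}: drifting block means "
                    f"({m1:.3f} vs {m2:.3f} kJ/mol)")
    return TIResult(lambdas, means, errs, warnings)


# ---------------------------------------------------------------------------
# umbrella sampling / WHAM
# ---------------------------------------------------------------------------

@dataclass
class PMFResult:
    """Stitched potential of mean force along a reaction coordinate."""

    bin_centers: np.ndarray          # nm
    pmf: np.ndarray                  # kJ/mol, zeroed at the reference
    window_histograms: np.ndarray    # (n_windows, n_bins)
    bias_centers: np.ndarray
    bias_constants: np.ndarray
    window_offsets: np.ndarray       # converged free energies f_i (kJ/mol)
    residual: float


def umbrella_pmf(window_samples, bias_centers, bias_constants,
                 temperature: float = 300.0, bin_width: float = 0.05,
                 reference_region=None, tol: float = 1e-10,
                 max_iter: int = 100000) -> PMFResult:
    """Weighted-histogram recombination of harmonically biased windows.

    window_samples: sequence of 1D arrays of reaction-coordinate samples,
    one per window, biased by (1/2) k_i (z - z0_i)^2.  The PMF is zeroed
    over ``reference_region`` = (lo, hi) (default: the lowest-PMF bin).
    Raises :class:`CoverageError` when the pooled histogram has an
    interior gap.
    """
    kT = units.KB * temperature
    samples = [np.asarray(s, float) for s in window_samples]
    centers0 = np.asarray(bias_centers, float)
    ks = np.asarray(bias_constants, float)
    if not (len(samples) == len(centers0) == len(ks)):
        raise ValueError("windows, centers and constants must match")
    lo = min(s.min() for s in samples)
    hi = max(s.max() for s in samples)
    nbins = max(2, int(np.ceil((hi - lo) / bin_width)))
    edges = np.linspace(lo, hi + 1e-12, nbins + 1)
    z = 0.5 * (edges[1:] + edges[:-1])
    hists = np.array([np.histogram(s, bins=edges)[0] for s in samples],
                     dtype=float)
    pooled = hists.sum(axis=0)
    occ = np.nonzero(pooled > 0)[0]
    empty = pooled[occ[0]:occ[-1] + 1] == 0
    # tolerate isolated empty bins (histogram noise); three or more
    # consecutive empty interior bins mean the windows do not overlap
    run = 0
    for k, e in enumerate(empty):
        run = run + 1 if e else 0
        if run >= 3:
            g1 = z[occ[0] + k]
            g0 = z[occ[0] + k - run + 1]
            raise CoverageError(
                f"umbrella windows leave an unsampled gap around "
                f"{g0:.3f}..{g1:.3f} nm")

    N = np.array([len(s) for s in samples], dtype=float)
    w = 0.5 * ks[:, None] * (z[None, :] - centers0[:, None]) ** 2
    bolz = np.exp(-w / kT)                     # (windows, bins)
    f = np.zeros(len(samples))                 # window free energies
    resid = np.inf
    for _ in range(max_iter):
        denom = (N * np.exp(f / kT)) @ bolz    # (bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, pooled / denom, 0.0)
        Znew = bolz @ P
        fnew = -kT * np.log(Znew)
        fnew -= fnew[0]
        resid = float(np.max(np.abs(fnew - f)))
        f = fnew
        if resid < tol:
            break

    with np.errstate(divide="ignore"):
        pmf = -kT * np.log(np.where(P > 0, P, np.nan))
    if reference_region is not None:
        lo_r, hi_r = reference_region
        mask = (z >= lo_r) & (z <= hi_r) & np.isfinite(pmf)
        if not mask.any():
            raise ValueError("reference region contains no sampled bins")
        pmf -= np.nanmean(pmf[mask])
    else:
        pmf -= np.nanmin(pmf)
    return PMFResult(z, pmf, hists, centers0, ks, f, resid)
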