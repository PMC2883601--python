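# Methods

## The model

`polwater` simulates the polarizable variant of the coarse-grained
MARTINI water bead.  One bead stands for four water molecules (72 amu).
It has three sites: a neutral Lennard-Jones centre **W** and two charged
satellites **WP** (+q) and **WM** (−q), each of mass 24 amu, constrained
at l = 0.14 nm from the centre.  The satellites carry no LJ interaction
and interact with the rest of the system through Coulomb forces only;
all three intramolecular pairs are excluded from nonbonded interactions,
so the satellites rotate freely around the centre.  The instantaneous
molecular dipole is q·|r_WP − r_WM| and ranges from 0 (satellites
coincident) to 2ql = 0.1288 e·nm = 6.2 D.  Orientational
polarizability — the reorientation and stretching of this dipole in the
local field — is what gives the model its dielectric response.

Production parameters: q = 0.46 e, l = 0.14 nm, WP–W–WM angle potential
with θ₀ = 0 and K = 4.2, W–W self-interaction at level III of the
interaction ladder (ε = 4.0 kJ/mol, σ = 0.47 nm), and a uniform Coulomb
screening constant ε_r = 2.5 (the standard single-site water variant
uses ε_r = 15).

### Angle potential: cosine-harmonic, not harmonic-in-θ

The WP–W–WM angle uses the cosine-harmonic form standard in this
force-field family,

    E(θ) = ½ K (cos θ − cos θ₀)²,

not the textbook harmonic ½K(θ−θ₀)².  Near θ₀ = 0 the cosine form is
quartic in θ and therefore much softer; the distinction is physically
decisive.  With the cosine form and K = 4.2 our engine reproduces the
production model's bulk density (we measure 1043 kg/m³ at 300 K) and
mean bead dipole (4.87 D on a 216-bead check, target 4.9 D); the strict
harmonic form with the same constant gives ≈1026 kg/m³ and 4.2 D.  Both
forms are implemented (a per-angle form flag); water and alkane angles
default to the cosine form.  The harmonic-in-θ force carries a 1/sin θ
factor, regularised by flooring sin θ at 10⁻⁶ and dropping to the
vanishing small-angle limit below 10⁻⁴ rad, since θ₀ = 0 makes the
near-collinear geometry common.

### Nonbonded interactions

LJ 12-6 with the well depth set by a symmetric interaction-level matrix
(levels O…IX mapping to ε = 5.6…2.0 kJ/mol; σ = 0.47 nm except level
IX's 0.62 nm).  The shipped YAML database holds the revised charged-type
(Q) rows of the polarizable variant in bold-face-equivalent form, the
original rows for the `standard` and `early` variants (`early` maps
Q–C1/C2 to level VIII), and the P4 row.  The polarizable water centre
interacts with P/N/C-class types at 95% of the P4-row well depth
(LJ well depth only, never σ); presets with 92% and 100% scaling exist
for solvation-free-energy comparisons.

Both LJ and Coulomb are smoothly shifted so that potential and force
vanish at the cutoff r_c = 1.2 nm: force
F(r) = α/r^(α+1) + A(r−r₁)² + B(r−r₁)³ for each power-law term, with A
and B fixed by F(r_c) = F'(r_c) = 0 and the potential its exact
antiderivative (zeroed at r_c).  LJ shifts from r₁ = 0.9 nm, Coulomb
from r₁ = 0; these are the canonical cutoffs of the force-field family.
Below r₁ the force is the bare power law and only the energy carries a
constant offset.  No long-range dispersion or electrostatic correction
is applied (short-ranged potentials are a deliberate property of the
model; lattice-sum electrostatics are out of scope).

## The engine

Leapfrog integration at dt = 20 fs (production), minimum-image
orthorhombic periodic boundaries on unwrapped coordinates, and a Verlet
pair list with 0.2 nm skin rebuilt by an O(N²) scan whenever any site
has moved more than skin/2.  At the in-scope system sizes (≤ ~11 000
sites, cutoff+skin a third of the box edge) cell binning would not
subdivide the box usefully, so the quadratic scan is the honest optimum.
The pair list is split into LJ-bearing and charged sublists with
precomputed per-pair parameters; a pair with both interactions appears
in both.

Constraints (the two satellite bonds) are solved by iterative
SHAKE-style pair corrections along the reference bond direction,
mass-weighted, to 10⁻⁶ nm (≤100 iterations).  The accumulated
multipliers supply the constraint contribution to the virial,
−(g/dt²)·s⊗s per constraint, and the position corrections are folded
into the half-step velocities.  Kinetic temperature uses
3N − N_constraints − 3 degrees of freedom (centre-of-mass motion is
removed every step).

Temperature and pressure use Berendsen weak coupling with τ_T = 0.3 ps
and τ_p = 3.0 ps (compressibility 4.5×10⁻⁵ bar⁻¹).  The thermostat
scale factor is computed from the post-constraint temperature of the
previous step (computing it pre-constraint biases the stationary
temperature low by a few K).  Pressure coupling is isotropic (`NPT`),
z-only at fixed area (`NPzAT`), or independent z/xy (`NPzPxyT`).  The
pressure tensor is (Σmv⊗v + Ξ)/V with Ξ the pair + bonded + constraint
virial.  A uniform external field E_z adds q·E_z·96.4853 kJ/mol/nm/e to
every charged site.

An optional Andersen-style interval (full Maxwell–Boltzmann velocity
re-draw every k steps) exists because Berendsen coupling is not
canonical for very small systems; the thermodynamic-integration oracle
tests (a handful of particles) use it.  It is off by default.

A harmonic umbrella bias ½k(z_COM − z₀)² on one molecule's z centre of
mass supports umbrella-sampling runs; the biased coordinate is logged
per record.  The bias is a sampling device and does not contribute to
the reported virial.

## Estimators

* **Density** — per-record total mass / box volume, block-averaged.
* **Dielectric constant** — ε = 1 + (⟨M²⟩−⟨M⟩²)/(3 ε₀ V k_B T) from the
  logged total dipole M = Σqᵢrᵢ, i.e. the fluctuation relation in its
  no-reaction-field (ε_rf → ∞) limit.  The run-time screening constant
  ε_r is *not* inserted into this formula; whether the original
  analysis folded an ε_r-dependent correction into it is not decidable
  from the published description, so the plain form is used and stated.
* **Bead dipoles** — q(r_WP − r_WM) per molecule, histogrammed in
  Debye (48.0321 D per e·nm); every magnitude is bounded by 2ql.
* **RDF** — shell-normalised minimum-image pair histogram; identical
  selections exclude self-pairs.
* **Surface tension** — γ = (L_z/2)(⟨P_zz⟩ − ⟨(P_xx+P_yy)/2⟩) over the
  logged pressure tensor of a z-normal slab; the factor 2 is the two
  interfaces; 1 bar·nm = 0.1 mN/m.
* **Diffusion** — MSD with multiple time origins (origin stride =
  fit-window/10), least-squares slope, D = slope/6.  Kinetic quantities
  are reported against effective time (CG dynamics run ≈4× fast): the
  per-bead D_CG uses t_eff = 4t, and the individual-molecule value is
  4·D_CG (a bead's centre-of-mass MSD is a quarter of the mean
  single-molecule MSD of the four molecules it represents).  The factor
  is always reported alongside and never applied to thermodynamic
  quantities.  Periodic jumps are healed by accumulating minimum-image
  frame-to-frame displacements, so wrapped trajectories analyse
  correctly.
* **Potential profile** — time-averaged charge density ρ(z), double
  integration of −ρ/ε₀ with φ = φ' = 0 at the lower box face, reported
  in volts.
* **Pore detection** — water LJ centres within (±0.3 nm of) the alkane
  slab's z-range, single-linkage clustered at 0.6 nm; a cluster touching
  both interfaces is a pore.  This makes the visual criterion of
  field-driven poration operational.

Statistical errors everywhere are block averages with ≥5 blocks.

## Free energies

Solvation/hydration free energies by thermodynamic integration:
H(λ) = λ·V(r_A) for solute–solvent pairs with the separation-shifted
soft core r_A = (r⁶ + α σ⁶ (1−λ))^(1/6), α = 0.5, λ-power 1, applied to
both LJ and Coulomb (σ-based radius shift; σ = 0.47 nm for pairs with
no LJ).  λ = 1 recovers the plain kernels exactly; λ = 0 decouples with
finite energy everywhere.  ∂H/∂λ is analytic.  The default grid is 22
evenly spaced λ points integrated by the trapezoid rule with
root-sum-square error propagation; window length, equilibration
fraction (default 25%) and grid size are configurable, and the defaults
here are desk-scale (the published protocol is 22 × 6 ns windows —
hours of compute; errors at shorter windows are reported honestly, not
hidden).  A window whose half means differ by >3 combined errors is
flagged as unequilibrated.  Partitioning free energies follow
ΔG_part = ΔG_hydr − ΔG_solv with ΔG_solv from the same machinery in the
organic-solvent box.

Umbrella-sampling windows are recombined by self-consistent WHAM
iteration to a 10⁻¹⁰ free-energy tolerance (residual reported); the PMF
is −k_BT ln P zeroed over a stated reference region.  Windows whose
pooled histogram leaves ≥3 consecutive empty interior bins raise a
coverage error naming the gap; isolated empty bins are tolerated as
histogram noise.

## System builders and the conditions they emulate

Builders place molecules on jittered FCC lattices (no LJ-centre pair
closer than 0.4 nm), polarizable satellites starting coincident at l
from the centre along a seeded random direction (zero initial molecular
dipole, the θ₀ = 0 equilibrium), and Maxwell–Boltzmann velocities
rescaled exactly to the target temperature after centre-of-mass
removal.  Everything is driven by one integer seed; identical arguments
give bit-identical systems.

Bulk boxes are cubic at a requested starting density; the satellite
charge q and angle constant K are exposed for parameterisation scans.
Slabs stack an alkane region and a water region along z (water/vacuum
leaves an empty region at least as thick as the water slab and ≥3 nm);
regions are inset 0.18 nm at the interfaces so no cross-species pair
starts inside the repulsive core, and a too-thin alkane slab is widened
to hold its chain lattice (pressure coupling relaxes it).  Alkanes are
linear C1 chains at the 4:1 mapping — butane 1 bead, octane 2,
hexadecane 4 — with harmonic bonds b₀ = 0.47 nm, k = 1250 kJ/mol/nm²
and cosine-harmonic angles (θ₀ = π, K = 25); these standard bonded
values and the 2-bead octane are this package's choices where the
original description is silent.  Ions are single 72-amu beads (Qd +1,
Qa −1) substituted for randomly chosen water beads.

What the synthetic systems do *not* emulate: lipid bilayers and any
membrane-derived observable, long-range (lattice-sum) electrostatics,
and liquid/ice coexistence.  Passing tests therefore demonstrate the
bulk and simple-interface physics of the water model, not membrane
behaviour.

## Problem sizes and validation scales

The package's own validation (test suite and the reproduction script)
uses desk-scale runs chosen to finish on one CPU core:

* Bulk density/dipole/diffusion: 400 beads, 1.5 ns NPT (0.5 ns
  equilibration discarded).  At this size the density at 300 K and
  350 K lands within a fraction of a percent of the published values,
  and the mean dipole within a few hundredths of a Debye.
* Parameterisation trends: 216-bead boxes, 0.8–1 ns each.  216 rather
  than the original 125-bead scan keeps half the box edge above
  r_cut + skin, which the engine enforces.
* Free-energy machinery: analytic oracles (ideal-gas solvent insertion
  against a radial quadrature; WHAM against a generating double-well)
  rather than the multi-hundred-ns published protocols.

The converged dielectric constant (75.6 at 300 K) needs ≳50 ns of
sampling and is validated here at the trend level (ordering in K_θ and
T) plus the closed-form recovery of the fluctuation estimator on
synthetic Gaussian dipole traces.  The 3708-bead/40 ns surface-tension
and the 22 × 6 ns hydration runs are reachable through the same public
API (`build_slab_system` + `NPzAT`/`NVT` + `surface_tension`;
`ti_run`) for anyone with the compute budget.

## Numerical choices and degenerate inputs

* Singularity guard: any interacting pair closer than 10⁻⁵ nm aborts
  with the pair named.
* Thermostat scale factor clamped to [0.8, 1.25], barostat scale to
  [0.98, 1.02] per step; a kinetic temperature above 10× target raises
  an integration error.
* SHAKE divergence names the molecule; already-satisfied constraints
  return unchanged to 10⁻¹² nm.
* GRO output wraps molecules as rigid units (anchor site in the box) so
  re-read configurations never split a constraint across the boundary;
  coordinates carry the format's native 3-decimal precision.
* The dielectric estimator requires ≥2 records and positive volumes;
  the RDF enforces r_max ≤ half the smallest box edge; the diffusion
  window must fit inside the trajectory.

## Known limitations

* Berendsen coupling does not generate a strict canonical/isobaric
  ensemble; for the bulk observables validated here the bias is far
  below the statistical noise, but small-system free-energy runs should
  enable the Andersen interval.
* The air/water surface tension of the underlying model is itself well
  below experiment (≈30 vs 73 mN/m) — a model property, not an
  implementation artefact.
* No lattice-sum electrostatics: observables sensitive to long-range
  Coulomb (e.g. ion PMFs) inherit the shifted-cutoff approximation.
* Single-threaded; the O(N²) neighbour rebuild makes >10⁵-site systems
  impractical.
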