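# Nonbonded parameter database for the coarse-grained force field.
#
# Bead types: W/WP/WM are the three sites of the polarizable water bead
# (neutral LJ centre plus two bound, oppositely charged satellites).
# P/N/C/Q are the standard MARTINI 4:1 chemical classes; DUM is an inert
# dummy site (no LJ, no charge) used for ideal-gas references.
#
# Interaction levels map a type pair to a Lennard-Jones well depth
# (kJ/mol).  sigma = 0.47 nm everywhere except level IX (0.62 nm).
# The "polarizable" block holds the revised charged-type rows; the
# "standard" block the original ones.  The W row against P/N/C types is
# generated at load time as 95% of the P4 row (LJ well depth only).

bead_types:
  W:   {mass: 24.0, charge: 0.0,   lj: true,  coulomb: false}
  WP:  {mass: 24.0, charge: 0.46,  lj: false, coulomb: true}
  WM:  {mass: 24.0, charge: -0.46, lj: false, coulomb: true}
  P5:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  P4:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  P3:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  P2:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  P1:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  Nda: {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  Nd:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  Na:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  N0:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  C5:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  C4:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  C3:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  C2:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  C1:  {mass: 72.0, charge: 0.0, lj: true, coulomb: false}
  Qda: {mass: 72.0, charge: 1.0,  lj: true, coulomb: true}
  Qd:  {mass: 72.0, charge: 1.0,  lj: true, coulomb: true}
  Qa:  {mass: 72.0, charge: -1.0, lj: true, coulomb: true}
  Q0:  {mass: 72.0, charge: 1.0,  lj: true, coulomb: true}
  DUM: {mass: 72.0, charge: 0.0, lj: false, coulomb: false}

levels:
  O: 5.6
  I: 5.0
  II: 4.5
  III: 4.0
  IV: 3.5
  V: 3.1
  VI: 2.7
  VII: 2.3
  VIII: 2.0
  IX: 2.0

sigma_default: 0.47
sigma_by_level:
  IX: 0.62

# Levels shared by every variant: the P4 row of the standard matrix
# (used directly for standard water, and as the base for the scaled
# polarizable-water cross interactions) plus the alkane self term.
common_pairs:
  P4,P4: I
  P4,P5: O
  P4,P3: I
  P4,P2: II
  P4,P1: II
  P4,Nda: III
  P4,Nd: III
  P4,Na: III
  P4,N0: IV
  P4,C5: V
  P4,C4: VI
  P4,C3: VI
  P4,C2: VII
  P4,C1: VIII
  C1,C1: IV

# Revised charged-type rows used with the polarizable water model.
polarizable_pairs:
  W,W: III
  W,Qda: O
  W,Qd: I
  W,Qa: I
  W,Q0: II
  Qda,Qda: O
  Qda,Qd: I
  Qda,Qa: I
  Qda,Q0: IV
  Qda,P5: O
  Qda,P4: O
  Qda,P3: O
  Qda,P2: O
  Qda,P1: O
  Qda,Nda: O
  Qda,Nd: O
  Qda,Na: O
  Qda,N0: III
  Qda,C5: IV
  Qda,C4: V
  Qda,C3: VI
  Qda,C2: VII
  Qda,C1: VII
  Qd,Qd: IV
  Qd,Qa: III
  Qd,Q0: VII
  Qd,P5: O
  Qd,P4: O
  Qd,P3: O
  Qd,P2: O
  Qd,P1: O
  Qd,Nda: O
  Qd,Nd: II
  Qd,Na: O
  Qd,N0: III
  Qd,C5: IV
  Qd,C4: V
  Qd,C3: VI
  Qd,C2: VII
  Qd,C1: VII
  Qa,Qa: IV
  Qa,Q0: VII
  Qa,P5: O
  Qa,P4: O
  Qa,P3: O
  Qa,P2: O
  Qa,P1: O
  Qa,Nda: O
  Qa,Nd: O
  Qa,Na: II
  Qa,N0: III
  Qa,C5: IV
  Qa,C4: V
  Qa,C3: VI
  Qa,C2: VII
  Qa,C1: VII
  Q0,Q0: IV
  Q0,P5: O
  Q0,P4: O
  Q0,P3: O
  Q0,P2: I
  Q0,P1: II
  Q0,Nda: II
  Q0,Nd: II
  Q0,Na: II
  Q0,N0: III
  Q0,C5: IV
  Q0,C4: V
  Q0,C3: VI
  Q0,C2: VII
  Q0,C1: VII

# Original charged-type rows (standard MARTINI water as type P4).
standard_pairs:
  Qda,Qda: O
  Qda,Qd: O
  Qda,Qa: O
  Qda,Q0: II
  Qda,P5: O
  Qda,P4: O
  Qda,P3: O
  Qda,P2: I
  Qda,P1: I
  Qda,Nda: I
  Qda,Nd: I
  Qda,Na: I
  Qda,N0: IV
  Qda,C5: V
  Qda,C4: VI
  Qda,C3: VII
  Qda,C2: IX
  Qda,C1: IX
  Qd,Qd: I
  Qd,Qa: O
  Qd,Q0: II
  Qd,P5: O
  Qd,P4: O
  Qd,P3: O
  Qd,P2: I
  Qd,P1: I
  Qd,Nda: I
  Qd,Nd: III
  Qd,Na: I
  Qd,N0: IV
  Qd,C5: V
  Qd,C4: VI
  Qd,C3: VII
  Qd,C2: IX
  Qd,C1: IX
  Qa,Qa: I
  Qa,Q0: II
  Qa,P5: O
  Qa,P4: O
  Qa,P3: O
  Qa,P2: I
  Qa,P1: I
  Qa,Nda: I
  Qa,Nd: I
  Qa,Na: III
  Qa,N0: IV
  Qa,C5: V
  Qa,C4: VI
  Qa,C3: VII
  Qa,C2: IX
  Qa,C1: IX
  Q0,Q0: IV
  Q0,P5: I
  Q0,P4: O
  Q0,P3: I
  Q0,P2: II
  Q0,P1: III
  Q0,Nda: III
  Q0,Nd: III
  Q0,Na: III
  Q0,N0: IV
  Q0,C5: V
  Q0,C4: VI
  Q0,C3: VII
  Q0,C2: IX
  Q0,C1: IX
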