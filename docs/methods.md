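# Methods

`pkfold` predicts three-dimensional folds, melting thermodynamics and
thermal unfolding pathways of small RNAs (hairpins and H-type
pseudoknots, roughly 10-60 nt) from sequence alone, in solutions of
monovalent and mixed monovalent/divalent salt.

## Coarse-grained representation

Each nucleotide is three beads: P on the phosphorus, C on the C4' sugar
atom, and N on the glycosidic nitrogen (N1 for C/U, N9 for A/G), with van
der Waals radii 1.9, 1.7 and 2.2 A and one negative elementary charge per
phosphate.  Coordinates are in Angstrom, energies in kcal/mol,
temperature in Kelvin internally and Celsius at every user interface.
Residue indices are 0-based in the API and 1-based in reports.

The geometric anchor of the model is an ideal A-form helix template: a
rise of 2.81 A and twist of 32.7 deg per nucleotide, with per-bead
cylindrical coordinates solved once (by least squares) so that the
template reproduces canonical A-RNA distances - adjacent P-P 5.9 A,
intra-residue P-C4' 3.8 A, C4'-P(next) 3.7 A, C4'-N 3.4 A, and a
glycosidic N-N separation of 8.9 A across a Watson-Crick pair whose
glycosidic vectors face each other.  The paired strand is the dyad image
(x, -y, -z) of the template strand.  All bonded equilibria, the
pairing-well minimum and the stacking geometry are measured from this
template and recorded in `src/pkfold/data/params.yaml`; the same template
generates the ideal-helix fixtures used by the tests, so geometric
self-consistency is checked rather than assumed.

## Energy function

The conformational energy is a sum of eight terms:

    U = U_b + U_a + U_d + U_exc + U_bp + U_bs + U_cs + U_el

- **U_b, U_a, U_d** (bonds, angles, dihedrals): harmonic wells for bonds
  and angles, `k (1 - cos(phi - phi0))` for dihedrals, over the
  P-C-N topology (bonds P-C, C-N, C-P(next); four angle types; three
  dihedral types).  Two parameter sets share the same equilibria but
  differ in stiffness: `nonhelical` (angles 1.5 kcal/mol/rad^2, dihedrals
  0.2 kcal/mol) governs the folding stage and single-stranded regions;
  `helical` (angles 2.0, dihedrals 0.35) is applied to base-paired
  residues during refinement.  The stiffening is deliberately moderate:
  with strongly stiffened helical wells, a frayed pair releases a large
  bonded penalty when its residues drop back to the soft set, which makes
  unpairing systematically favorable and unravels folds during
  refinement.  For the same reason the helical/nonhelical labels are
  frozen at refinement entry (from the annealed fold's pair map) rather
  than refreshed as pairs fluctuate.
- **U_exc**: purely repulsive soft spheres,
  `eps [(s/r)^12 - 2 (s/r)^6 + 1]` for r below the contact distance
  s = R_i + R_j, zero beyond; 1-2 and 1-3 neighbors are excluded.
- **U_bp** (base pairing): for each formed pair, a Gaussian well in the
  N-N distance (minimum at the template value 8.72 A, width 2 A, support
  +-6 A) multiplied by two orientation factors: a facing factor (the
  glycosidic vectors must point at each other, normalized so the template
  geometry scores 1) and an antiparallel gate that ramps the interaction
  to zero as the local backbone tangents of the two partners become
  parallel.  Without the gate the sampler readily forms parallel-strand
  "ladders" that satisfy any distance-plus-facing criterion but do not
  exist in RNA.  Well depths are per pair class (GC 2.8, AU 2.0, GU 1.5
  kcal/mol), calibrated - see below.  Which pairs are "formed" is decided
  geometrically from the same criterion (complementarity incl. GU
  wobble, at least 3 intervening nucleotides, distance and orientation
  windows), with conflicts resolved greedily by best pairing energy so
  each base has at most one partner.  The energy function evaluates the
  pair map over the full well support; the narrower reporting window
  (3 A, facing >= 0.3) defines the pair counts written to trajectories.
- **U_bs** (base stacking): every formed dinucleotide step
  (i,j)/(i+1,j-1) contributes `G(T) = dH - T dS` from the Turner/Xia
  nearest-neighbor table (steps containing a GU pair use one generic
  increment), multiplied by a Gaussian in the distance between the two
  pair centroids (minimum at the template step distance 3.50 A) and a
  global scale factor.  The temperature dependence of G(T) is what melts
  helices as T rises.
- **U_cs** (coaxial stacking): two stems of at least 2 bp whose
  interfacial pairs are bridged by at most 1 unpaired nucleotide in
  sequence and sit in stacking geometry gain the nearest-neighbor G(T) of
  the pseudo-step formed by the two interface pairs.  Both possible
  junction sides of an H-type fold are examined and the most stabilizing
  geometric arrangement is used (only one interface can stack at a time).
  The minimum stem length matters: without it, any two adjacent lone
  pairs in a collapsed coil masquerade as "stems" and the term becomes a
  strong spurious attractor for misfolds.  A flag disables the term for
  ablation studies.
- **U_el** (electrostatics): screened Coulomb repulsion
  `332.06 Q^2 / (eps_r(T) r) exp(-r/lambda_D)` between phosphate pairs at
  backbone separation >= 2.  The dielectric constant of water follows the
  standard empirical polynomial in temperature; the Debye length is
  computed from the ionic strength I = c1 + 3 c2 (mol/L).  The effective
  charge Q per phosphate comes from Manning condensation, Q = 1/(z xi)
  with xi = l_B/b and an axial spacing b per structure state (coil
  4.4 A - the default during simulations - or helix 1.7 A).  Divalent
  competition interpolates between the monovalent-only and
  divalent-dominated limits with a binding fraction
  x = a sqrt(c2) / (a sqrt(c2) + c1); the single coefficient a = 1.7
  reproduces the qualitative behavior that sub-millimolar Mg2+ against
  ~50 mM K+ already shifts stability substantially and saturates at high
  Mg2+.  At c2 = 0 the model reduces bit-exactly to the monovalent-only
  formulation.

## Sampling

Conformations evolve by pivot moves: a uniformly random pivot residue, a
side (5' or 3' arm), a uniformly random axis through the pivot's sugar
bead and a rotation angle uniform in [-theta_max, +theta_max].  The move
is rigid (bond lengths in the rotated arm are preserved exactly) and
symmetric, so the standard Metropolis rule `min(1, exp(-dU/kB T))` leaves
the Boltzmann distribution invariant.  The full energy is recomputed per
proposal (vectorized numpy; an exact function of coordinates, no
incremental bookkeeping to drift), and the decomposition identity is
re-asserted from scratch every 10^4 steps.

Folding runs simulated annealing from a self-avoiding random chain
(grown from bond lengths plus excluded volume only): by default 130 C
down to 25 C with the nonhelical bonded set and the ion condition held
fixed; theta_max is adapted between temperature steps toward a 30-50%
acceptance window.  Refinement then runs fixed-temperature MC from the
annealed fold with paired residues on the helical set (mask frozen at
entry), recording a structure ensemble for RMSD evaluation.

## Melting analysis

Stability comes from per-temperature trajectories, by default
independent fixed-T runs restarted from the annealed fold (the recorded
cooling trajectory can be reused instead via `protocol="cooling"`; an
explicitly supplied `initial_chain` -- e.g. a constructed reference fold
-- skips the annealing search entirely, which separates the
thermodynamics question from the conformational-search question at small
sampling budgets); the
first 25% of frames at each temperature are discarded as equilibration.
Reduced-sampling scans carry several degrees of stochastic scatter in
the fitted melting temperatures; comparisons across conditions (e.g.
salt series) should average Tm over replicate scans, as the shipped
acceptance checks do.
Frames are classified against the two reference stems of the folded
structure: a stem counts as formed iff at least 50% of its reference
pairs are present (inclusive), giving F (both), S1/S2 (only Stem 1/2) and
U (neither).  For single-stem references the same machinery degrades to
a two-state F/U classification.  The folded and unfolded fractions are
fitted independently by least squares to

    f_F(T) = 1 / (1 + exp((T - Tm1)/dT1))
    f_U(T) = 1 - 1 / (1 + exp((T - Tm2)/dT2))

with Tm guesses at the empirical half-crossings, dT guesses of 5 C and
bounds Tm within the scanned range +-50 C, dT in (0.1, 50).  The
denatured-base-pair fraction and its analytic derivative are

    f(T) = 1 - [(1 - f_I) f_F(T) + f_I (1 - f_U(T))],

where f_I is `1 - <n_bp(T*)>/n_bp(folded)` at the temperature T*
maximizing the intermediate population (falling back, with a warning, to
the (Tm1+Tm2)/2 midpoint when the intermediate never peaks in the
interior).  df/dT is differentiated from the fitted logistics, not from
finite differences of noisy data.

## Structure evaluation

RMSD is computed over C beads against the reference C4' positions after
optimal least-squares superposition (quaternion/SVD solution; proper
rotations only, reflections disallowed), with correspondence strictly by
residue index - inputs of unequal length are rejected rather than
aligned.  Ensembles report per-member, mean and minimum RMSD and the
index of the best member.

## Calibration and what the defaults mean

All numbers live in `params.yaml`.  Three groups:

1. **Transcribed**: nearest-neighbor dH/dS (Turner/Xia), bead radii,
   physical constants, the dielectric polynomial.
2. **Template-derived**: bonded equilibria, pairing r0, stacking r0,
   orientation references - all measured from the solved A-form template.
3. **Calibrated**: pairing depths, well widths, the antiparallel gate,
   excluded-volume strength, stacking scale, helical stiffening, the Mg
   competition coefficient, annealing defaults.  These were tuned once,
   before the test expectations were frozen, against two qualitative
   requirements: a 10-nt GC hairpin must fold to its minimum pair set
   from random starts at 25 C / 1 M salt within short anneals, and must
   be molten at ~100 C.  They are model constants, not measurements.

Default problem sizes (6 temperature steps of a few thousand proposals
for toy chains; 10-20 k proposals per temperature in melting scans) are
the package's test/demonstration scale.  Production use - longer chains,
tighter convergence - simply raises `steps_per_temp` and the number of
scanned temperatures; the algorithms are unchanged.

## What the synthetic fixtures do and do not show

The synthetic module generates ideal template helices and hairpins (for
geometry and detection tests), toy hairpin/pseudoknot sequences, planted
three-state melting data (exact logistic fractions, and sampled
trajectories with known state labels) and synthetic CG-PDB files.
Passing tests on these fixtures demonstrates internal consistency -
detection finds constructed pairs, fits recover planted parameters,
refinement preserves constructed folds - and qualitative agreement with
the physics (salt and temperature trends).  They do not demonstrate
quantitative agreement with experimental melting temperatures or
experimental 3D structures, which requires production-scale sampling and
experimental references that are deliberately outside the offline test
suite.

## Known limitations

- No noncanonical interactions: no base triples, no loop-stem contacts,
  no loop self-stacking; pseudoknots stabilized by such contacts will be
  under-stabilized.
- Implicit ions only; Mg2+ enters through a mean-field charge-competition
  fit and may underestimate stabilization at high [Mg2+].
- The two-state logistic analysis assumes well-separated sigmoidal
  transitions; strongly overlapping transitions yield correlated (Tm, dT)
  estimates.
- Single chains only; no multi-chain complexes, no modified nucleotides,
  no mechanical force, no all-atom reconstruction.
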