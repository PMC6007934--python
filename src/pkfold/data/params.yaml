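# Default force-field parameters for the three-bead coarse-grained RNA model.
#
# Units: kcal/mol, Angstrom, Kelvin, degrees (angles/dihedrals as noted).
# Bonded equilibria are fitted to the ideal A-form CG helix defined by
# `helix_template` (itself solved from canonical A-RNA distances: P-P 5.9 A,
# rise 2.81 A, twist 32.7 deg, glycosidic N-N 8.9 A across a Watson-Crick
# pair).  Nearest-neighbor stacking dH/dS are the Turner/Xia experimental
# increments.  Pairing-well depths and the divalent-competition coefficient
# are calibrated model constants, not experimental measurements.
version: 1

beads:
  radii: {P: 1.9, C: 1.7, N: 2.2}     # van der Waals radii, Angstrom
  phosphate_charge: -1.0              # bare charge per P bead, units of e

helix_template:
  rise: 2.81                          # Angstrom per nucleotide
  twist_deg: 32.7                     # 11 bp per turn
  # cylindrical coords [r, phi_deg, z] of nucleotide-0 beads; the duplex
  # partner strand is the dyad image (x, -y, -z).
  cylindrical:
    P: [9.2643, 36.9058, 0.7451]
    C: [8.8726, 60.6723, 0.1577]
    N: [5.7189, 49.5507, 0.2869]

bonded:
  # bonds: [r0 (A), k (kcal/mol/A^2)]; angles: [theta0 (deg), k (kcal/mol/rad^2)]
  # dihedrals: [phi0 (deg), k (kcal/mol)] with U = k * (1 - cos(phi - phi0))
  helical:
    bonds:
      PC: [3.8000, 20.0]
      CP: [3.7000, 20.0]
      CN: [3.4450, 20.0]
    angles:
      PCP: [104.3542, 2.0]
      CPC: [99.6618, 2.0]
      PCN: [65.2573, 2.0]
      NCP: [99.2965, 2.0]
    dihedrals:
      PCPC: [147.3015, 0.35]
      CPCP: [-167.8162, 0.35]
      NCPC: [80.6231, 0.35]
  nonhelical:
    # same equilibria (single strands keep local connectivity geometry) but
    # much softer angular/torsional wells so loops and coil are flexible
    bonds:
      PC: [3.8000, 20.0]
      CP: [3.7000, 20.0]
      CN: [3.4450, 20.0]
    angles:
      PCP: [104.3542, 1.5]
      CPC: [99.6618, 1.5]
      PCN: [65.2573, 1.5]
      NCP: [99.2965, 1.5]
    dihedrals:
      PCPC: [147.3015, 0.2]
      CPCP: [-167.8162, 0.2]
      NCPC: [80.6231, 0.2]

excluded_volume:
  epsilon: 0.26                       # kcal/mol; purely repulsive below contact
  overlap_tolerance: 0.5              # allowed soft overlap (A) in chain growth

pairing:
  r0: 8.7229                          # N-N distance at the well minimum (A)
  sigma: 2.0                          # Gaussian well width (A)
  cutoff_offset: 6.0                  # well support: |d - r0| <= cutoff_offset
  detect_window: 3.0                  # |d - r0| window for counting a formed pair
  orientation_ref: 0.9319             # -u_i.u_j of the ideal pair (normalizes facing)
  orientation_detect_min: 0.3         # minimum facing factor to count a pair
  # antiparallel gate: pairing switches off as the two local backbone
  # tangents become parallel (their dot is ~0.13 in the ideal duplex, ~1 in
  # a forbidden parallel ladder); linear ramp 1 -> 0 over [lo, hi]
  antiparallel_lo: 0.35
  antiparallel_hi: 0.75
  min_loop: 3                         # >= 3 intervening nt (j - i >= 4)
  depth: {GC: 2.8, AU: 2.0, GU: 1.5}  # well depths, kcal/mol (calibrated)

stacking:
  # step free energy G(T) = dH - T*dS applied between adjacent base pairs,
  # modulated by a Gaussian in the distance between the two pair centroids
  # and a global scale (calibrated: ladder cooperativity of this CG
  # geometry needs more than the bare nearest-neighbor increments).
  scale: 1.5
  r0: 3.5016                          # ideal adjacent pair-centroid distance (A)
  sigma: 2.0
  cutoff_offset: 5.0
  # Watson-Crick nearest-neighbor increments, [dH (kcal/mol), dS (cal/mol/K)]
  table:
    AA/UU: [-6.82, -19.0]
    AU/AU: [-9.38, -26.7]
    UA/UA: [-7.69, -20.5]
    CU/AG: [-10.48, -27.1]
    CA/UG: [-10.44, -26.9]
    GU/AC: [-11.40, -29.5]
    GA/UC: [-12.44, -32.5]
    CG/CG: [-10.64, -26.7]
    GG/CC: [-13.39, -32.7]
    GC/GC: [-14.88, -36.9]
  gu_step: [-8.0, -21.9]              # generic increment for steps with a GU pair

coaxial:
  enabled: true
  max_junction_loop: 1                # nt; coaxial stacking only across <=1-nt junction
  min_helix_length: 2                 # bp; lone pairs are not helices and cannot coax-stack
  r0: 3.5016                          # interface pair-centroid distance (A)
  sigma: 2.0
  cutoff_offset: 5.0
  scale: 1.0                          # multiplies the interface-step G(T)

electrostatics:
  enabled: true
  coulomb_const: 332.0637             # kcal*A/(mol*e^2)
  bjerrum_const: 166937.0             # e^2/(4 pi eps0 kB) in A*K; l_B = this/(eps_r*T)
  divalent_strength_weight: 3.0       # ionic strength I = c1 + w*c2
  # Manning axial charge spacings (A) by structure state; sets the condensed
  # charge fraction 1/(z*xi), xi = l_B / b
  manning_spacing: {coil: 4.4, helix: 1.7}
  divalent_competition_a: 1.7         # binding fraction x = a*sqrt(c2)/(a*sqrt(c2)+c1)
  min_backbone_separation: 2          # include P_i,P_j only if |i-j| >= 2

constants:
  kB: 0.0019872                       # kcal/(mol*K)
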