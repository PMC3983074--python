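# Parameter tables for the gadock empirical scoring function.
#
# These are this package's own documented defaults, calibrated on the toy
# fixture systems; they follow common medicinal-chemistry conventions
# (Bondi-style radii, Lorentz-Berthelot mixing, 3-fold torsional terms).

term_weights:
  inter: 1.0
  intra: 1.0
  site: 1.0
  restraint: 1.0
  vdw: 1.0
  polar: 1.0
  desolv: 0.5
  dihedral: 1.0

# van der Waals radii (Angstrom), used for steric accessibility and SASA
vdw_radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
  Cl: 1.75
  Br: 1.85
  I: 1.98
  default: 1.70

# pair-potential well parameters per element: r0 is the pair-minimum distance
# for a like pair (Angstrom), eps the well depth (score units).  Mixing:
# arithmetic mean on r0, geometric mean on eps.
vdw_well:
  H:  {r0: 2.6, eps: 0.02}
  C:  {r0: 3.6, eps: 0.15}
  N:  {r0: 3.3, eps: 0.16}
  O:  {r0: 3.2, eps: 0.16}
  S:  {r0: 3.8, eps: 0.20}
  P:  {r0: 3.8, eps: 0.20}
  F:  {r0: 3.1, eps: 0.10}
  Cl: {r0: 3.6, eps: 0.25}
  Br: {r0: 3.8, eps: 0.30}
  I:  {r0: 4.1, eps: 0.35}
  default: {r0: 3.5, eps: 0.15}
  metal: {r0: 2.8, eps: 0.30}

# empirical polar (hydrogen-bond) term
polar:
  well_depth: 8.0          # favourable donor-acceptor weight W, score units
  repulsive_weight: 2.5    # donor-donor / acceptor-acceptor clash (SF3)
  charged_multiplier: 2.0  # applied once per charged partner
  distance_window: [2.6, 3.0]   # donor-heavy ... acceptor, Angstrom
  donor_angle_window: [150.0, 180.0]    # D-H...A angle, degrees
  acceptor_angle_window: [110.0, 180.0] # H...A-root angle, degrees

# desolvation term: per-class weights for (SASA_bound - SASA_free), score/A^2.
# Positive apolar weight -> burying apolar surface is favourable; negative
# polar weights -> burying polar surface costs.
desolvation_weights:
  "apolar": 0.010
  "acceptor": -0.006
  "polar-H carrier": -0.006
  "donor-H": -0.003
  "metal": -0.010
  "other": 0.0

# probabilistic SASA (pairwise overlap product approximation); the p
# parameters are this package's own fit against a sphere-sampling SASA
# reference over the toy-molecule generator output
sasa:
  solvent_radius: 1.4
  p_atom:            # per-element scaling of the overlap reduction
    H: 0.376
    C: 0.654
    N: 0.605
    O: 0.371
    S: 0.654
    default: 0.60
  p_bonded: 2.5      # 1-2 neighbours
  p_nonbonded: 0.40
  distance_floor: 0.05

# 3-fold torsional barriers (score units) by central-bond element pair
torsion_barriers:
  C-C: 0.6
  C-N: 0.4
  C-O: 0.35
  default: 0.4

interaction_rules:
  metals: [Li, Na, K, Rb, Cs, Mg, Ca, Sr, Ba, Zn, Mn, Fe, Co, Ni, Cu, Cd, Hg, Al]
  polar_h_roots: [N, O, S]
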