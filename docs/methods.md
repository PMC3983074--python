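# Methods

This note documents the models and algorithms implemented in `gadock`, the
choices behind their default parameters, and what the synthetic test
systems do and do not demonstrate.

## Molecular model and perception

Molecules are bonded atom graphs with 3-D coordinates (Å), formal charges
and, for SD input, verbatim data fields. Receptors come from Tripos MOL2
(waters, ions and cofactors are kept as receptor atoms; partial charges are
read but not used by scoring, which depends on formal charges only);
ligands come from MDL SDF V2000 with formal charges taken from `M  CHG`
property lines. Record splitting and data fields are handled directly so a
parse→write→parse round trip preserves field text byte-identically; ring
and aromaticity perception, SMARTS matching and graph automorphisms are
delegated to RDKit.

Every atom carries exactly one interaction class — `donor-H` (H on N/O/S),
`acceptor` (lone-pair N/O/S), `polar-H carrier` (heavy atom bearing a polar
H that is not itself typed as an acceptor, e.g. amine or ammonium
nitrogen), `apolar` (C, halogens, H on C), `metal`, `other` — plus separate
positive/negative-centre flags. Carboxylate-style groups mark both
oxygens negative (delocalised charge). The rule table lives in
`src/gadock/data/params.yaml` and can be extended without code changes.

Ligand rotatable bonds are the single, acyclic bonds between two
non-terminal heavy atoms, excluding amide C–N bonds and rotors that move
only apolar hydrogens (methyl/CF3); rotors moving polar hydrogens (O–H,
N–H) are kept because they move the polar term. Ring-internal geometry is
never altered — flexible-ring conformers are expected to be enumerated
upstream. Receptor flexibility is restricted to terminal hydroxyl and
ammonium torsions, optionally filtered to groups within a margin of the
docking volume; water O–H rotation is off by default.

Because the rotated sets of distinct acyclic bonds are either nested or
disjoint, and the atoms of any other torsion that lie outside a rotated set
are on its rotation axis, setting one dihedral never changes the measured
value of another. Torsions can therefore be applied in any order, one
exact rotation each — the chromosome decoder relies on this.

## Cavity mapping

Two mapping algorithms produce the boolean docking-volume lattice (default
spacing 0.5 Å, a compromise between fidelity and memory):

* **reference ligand** — grid points within a radius (default 6 Å) of any
  reference-ligand heavy atom that are sterically accessible (no receptor
  heavy atom closer than its Bondi-style vdW radius plus a 1.4 Å probe
  allowance); connected components not overlapping the reference are
  discarded.
* **two probe spheres** — points reachable by a small probe (1.5 Å) but
  sheltered from bulk solvent; "open" solvent is found by flood-filling
  large-probe-accessible space (default large probe 6 Å, here re-derived
  from the two-probe principle rather than copied from any particular
  implementation) from the search-sphere boundary and dilating by the large
  probe radius. The finite search sphere can leave sheltered shards at its
  rim, so only the connected component closest to the requested centre is
  kept.

Distance-to-cavity queries are exact nearest-inside-grid-point distances
(zero within half a spacing). Two interchangeable implementations exist —
a KD-tree over the inside points and a compiled expanding-shell search over
the lattice — and the tests pin their equivalence.

## Scoring function

The total is a weighted sum

S_total = w_inter·S_inter + w_intra·S_intra + w_site·S_site + w_restraint·S_restraint

with all weights defaulting to 1. `S_inter` = vdW + polar
(+ desolvation under SF5); `S_intra` is the ligand's internal vdW + polar +
torsional energy **relative to its input conformation** (exactly 0 there by
construction); `S_site` is the flexible-receptor analogue; `S_restraint`
collects the cavity-containment and bias penalties. Two named
configurations exist: SF3 (default; repulsive polar on, desolvation off)
and SF5 (attractive-only polar, desolvation on).

**vdW.** n–m pair potential `eps·[(r0/r)^2m − 2(r0/r)^m]`, m = 6 for the
final 6-12 form and m = 4 for the soft 4-8 form used early in the search.
Per-element well parameters with arithmetic/geometric (Lorentz–Berthelot
style) mixing; energies capped at +100 to keep the stochastic search
numerically sane. Intra-ligand pairs at graph distance 1-2/1-3 are
excluded and 1-4 pairs scaled by 0.5. The receptor field can be
precalculated on per-ligand-class lattices (value at a lattice point equals
the direct capped pair sum exactly; off-lattice lookups are trilinear).

**Polar.** For each donor-H/acceptor pair,
`E = −W · f_d(|D−A|) · f_a(θ_DHA) · f_a(φ_HAR)` where the `f` are
trapezoidal ramps: 1 inside the ideal window, falling linearly to 0 across
a tolerance band. Defaults: distance window 2.6–3.0 Å (donor heavy atom to
acceptor), donor angle ≥ 150°, acceptor angle ≥ 110°, tolerances 0.6 Å /
30°, well depth W = 8. Donor–donor and acceptor–acceptor contacts
contribute a distance-only repulsion (weight 2.5) under SF3. Each charged
partner doubles the magnitude. The window widths were chosen so that the
favourable set is tight enough to define unique toy binding modes yet wide
enough that the ramps provide a capture gradient for the local
optimisers; tightening the flat-top much further makes the landscape
needle-like and the search unreliable, widening it makes distinct poses
degenerate.

**Desolvation (SF5).** `Σ_i w_class(i)·(A_i^bound − A_i^free)` over ligand
and receptor atoms, with A from a probabilistic pairwise-overlap SASA:
`A_i = S_i·Π_j (1 − p_i·p_ij·b_ij/S_i)`, `S_i = 4π(r_i+1.4)²`, `b_ij` the
pairwise sphere-overlap area. The `p` parameters shipped in the data file
are this package's own least-squares fit against a sphere-sampling SASA
reference over generated test molecules (per-atom Pearson r ≈ 0.96); they
are not anyone else's published values. Positive apolar weight makes
burial of apolar surface favourable; polar burial costs.

**Torsional.** 3-fold cosine `V/2·(1+cos 3θ)` per rotatable bond with
barriers by central-bond element pair (0.35–0.6).

## Search

The chromosome is (ligand COM; heading/attitude/bank Euler angles rotating
the ligand principal axes from the lab axes, Tait–Bryan z-y'-x'', with the
principal frame sign-fixed by a first-atom rule so encoding is unique;
ligand rotatable dihedrals; receptor rotatable dihedrals). A docking run
is GA1 → GA2 → GA3 → MC → MIN:

| stage | vdW form | polar tolerance × | dihedral weight × |
|-------|----------|-------------------|-------------------|
| GA1   | 4-8      | 2.0               | 0.25              |
| GA2   | 4-8      | 1.5               | 0.5               |
| GA3   | 6-12     | 1.25              | 0.75              |
| MC/MIN| 6-12     | 1.0               | 1.0               |

Population initialisation puts the COM on a uniformly chosen cavity grid
point and draws orientation and dihedrals uniformly. The GA is
steady-state with linear-rank selection, per-gene uniform crossover, and
single-degree-of-freedom mutations drawn from rectangular distributions
(widths 2 Å / 30°); children replace the current worst individual only if
better, which preserves the best (elitism) and makes the best-score trace
non-increasing. A generation has passed when as many children have been
created as the population size (default 50 plus 4 per rotatable bond); the
stage stops when the best score improved by less than 0.1 over the last
three generations (checked as soon as three generations exist). MC is 500
steps of single-DOF Metropolis at temperature 0.5 with 1 Å / 20° moves,
returning the best-seen state (the wider moves let MC hop the small
barriers between adjacent near-optimal poses that the GA leaves behind);
MIN is adaptive Nelder–Mead over the chromosome vector (tolerance
1e-4, at most 2000 evaluations, initial simplex steps 0.3 Å / 5°). A
docking campaign repeats the pipeline n_runs times (default 50) with
independent seeded generators and reports poses sorted by the final-stage
score; score-only and minimise-only entry points bypass the search.

Multi-step screening protocols take a list of (cumulative runs, score
threshold) stages; ligands whose best score misses a threshold stop
sampling. Per-run seeds depend only on (master seed, ligand, run index),
so a staged protocol is bit-identical to an uninterrupted campaign, and a
single-stage protocol reproduces plain docking exactly.

In tethered mode the rigid-body genes are reinterpreted as the matched
substructure's translation (clamped to 0.1 Å) and rotation vector (clamped
to 1°) about the substructure centroid; dihedrals whose rotation would move
matched atoms are re-oriented to the free side or frozen. The tether is
thus enforced absolutely by the move set, never by a penalty;
`tether_violation` exists only to verify emitted poses. Substructure
matches are enumerated exhaustively and collapsed when two alignments are
indistinguishable (symmetry-corrected RMSD < 0.15 Å), so only genuinely
distinct orientations are docked.

## Restraints

Pharmacophore restraints are tolerance spheres per feature type (eight
types: neutral HBA/HBD, hydrophobic, aliphatic, aromatic — ring centroids —
negative, positive, any heavy atom). Penalty `W·max(0, d−r)²` from the
nearest matching feature to the sphere surface; the total adds all
mandatory restraints and the N_opt smallest optional ones; ligands that
cannot satisfy the set even in the best case are screened out before
docking. The cavity penalty is `Σ W·d²` over heavy atoms outside the
docking volume. Distance restraints penalise the minimum selected-pair
distance quadratically beyond the bound; upper-bound (NOE-style) semantics
are the default with a lower-bound switch, since "a minimum distance is
fulfilled" can be read either way.

## Analysis

Symmetry-corrected RMSD minimises the heavy-atom RMSD over all
element/bond-order-preserving graph automorphisms (RDKit self-matching,
capped at 1e5 mappings with a warning), with no re-superposition —
reference and pose are compared in the docking frame. Multi-fragment
records use the largest fragment. The SD utilities filter by boolean
field expressions (numeric comparison when both sides parse as numbers),
sort stably, and report RFC-4180 CSV / TSV. Enrichment metrics sweep the
ROC with tied scores as blocks (AUC = Mann–Whitney statistic); logAUC is
the area under TPR vs log10(FPR) on [1e-3, 1] normalised by the axis width,
so a random ranking scores ≈ 0.145; EF(x) rounds the selection to the
nearest compound; EFmax is the maximum EF over all top-k prefixes.

## Synthetic test systems

The generator builds small organic molecules (chain graphs with requested
rotor counts and feature inventories; RDKit ETKDG geometry, deterministic
under the seed) and wraps a receptor "mould" around a chosen conformation:
carbon pseudo-atoms on the outward surface of the union of spheres at the
C–C pair-optimal distance (3.6 Å) from every ligand heavy atom, with an
opening toward +z, plus complementary polar sites — a bare acceptor oxygen
2.8 Å along each ligand donor-H direction, and a neutral N–H donor 2.8 Å
along each ligand acceptor's lone-pair direction with the hydrogen pointing
back. Donor and acceptor wall chemistry is deliberately asymmetric (an
N–H donor cannot accept) and ligands carry at most one acceptor anchor and
one donor group, so hydrogen-bond assignments cannot swap between
near-equivalent sites; this is what makes the constructed optimum unique
rather than one of a degenerate family. The wrapped pose is refined by
Simplex and cross-checked by a multi-run reference docking; the stored
optimum is the best pose found by this documented protocol (for flexible
ligands this is best-found, not a global-optimality claim) and the stored
ligand's input conformation is that optimum, as in a standard redocking
setup.

What the toys do **not** emulate: real protein chemistry and force-field
realism, induced fit, solvent structure, charged networks, or the size of
real binding sites. Passing the redocking and screening checks shows the
search machinery reliably recovers well-defined optima in funnel-shaped
landscapes of realistic dimensionality (0–8 rotors), not that the scoring
function ranks real protein–ligand complexes correctly.

## Numerical choices

* Short-range vdW cap +100; 1-4 scaling 0.5; SASA pair-distance floor
  0.05 Å.
* Grid lattices cover the cavity bounding box + 4 Å margin; lookups are
  trilinear; grid form (4-8/6-12) must match the active scoring stage.
* Convergence window: best score, three generations, 0.1 units (population
  best, not mean).
* Compiled kernels (numba) are exact twins of the closed-form Python
  terms; tests pin their agreement to 1e-9, and the cavity-distance
  lattice search is tested for exact equivalence with the KD-tree route.
* Determinism: every stochastic component draws from generators derived
  from an integer master seed via `SeedSequence`; two identical calls give
  byte-identical SD output.

## Known limitations

* The scoring parameters are calibrated for the toy systems, not against
  experimental affinities; absolute score values carry no physical units.
* Amine/ammonium nitrogens are not treated as H-bond acceptors, and metals
  participate only through vdW; both are acceptable for the toys but crude
  for real systems.
* The probabilistic SASA underestimates burial from dense non-bonded cages
  (correlation with the sphere-sampling reference is ~0.96 on molecules,
  worse for artificial clusters).
* Interstitial-water sampling and receptor-ensemble docking are out of
  scope.
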