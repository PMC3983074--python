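"""Biased docking: pharmacophore restraints and a tethered scaffold.

A pharmacophore restraint is a tolerance sphere that a ligand feature of a
given type must occupy; poses outside pay a quadratic penalty.  Tethering
constrains a SMARTS-matched substructure to reference coordinates within
small translation/rotation tolerances, enforced during pose generation.
"""

import numpy as np

from gadock.fixtures import make_redocking_suite
from gadock.restraints import (PharmacophoreRestraint, RestraintSet,
                               TetherSpec, detect_features,
                               screen_ligand_features, tether_violation)
from gadock.search import dock

cx = make_redocking_suite(1, seed=11, rotor_counts=[2], ref_runs=0)[0]

# place an HBA restraint sphere on the acceptor position of the optimum
feats = detect_features(cx.ligand)
center = feats["neutral HBA"][0]
rs = RestraintSet([PharmacophoreRestraint("neutral HBA", center, 1.5)])
print("ligand passes feature screening:",
      screen_ligand_features(cx.ligand, rs))
res = dock(cx.ligand, cx.receptor, cx.cavity, rs, n_runs=5, seed=1)
print(f"pharmacophore-restrained best score {res[0].breakdown.total:.2f}, "
      f"restraint term {res[0].breakdown.restraint:.3f}")
# a restraint term of 0 means the acceptor sits inside the tolerance sphere

# tether the first four heavy atoms to their coordinates in the optimum
mapping = tuple(int(i) for i in cx.ligand.molecule.heavy_indices[:4])
spec = TetherSpec("*~*~*~*", cx.ligand.molecule.coords[list(mapping)],
                  mapping=mapping)
res = dock(cx.ligand, cx.receptor, cx.cavity, RestraintSet(tether=spec),
           n_runs=3, seed=1)
t, r = tether_violation(res[0].pose, spec, mapping)
print(f"tethered best score {res[0].breakdown.total:.2f}; substructure "
      f"deviation {t:.3f} A translation, {r:.3f} deg rotation")
# tethering is enforced absolutely in the move set, so deviations stay
# within the 0.1 A / 1 degree defaults for every generated pose
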