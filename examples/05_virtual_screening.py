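"""A miniature virtual screen with enrichment metrics and HTVS staging.

Docks a small library (the pocket's true ligand plus decoys) into one toy
pocket, ranks by score, and computes ROC/enrichment metrics.  Then runs the
same library through a multi-step protocol that stops sampling poor scorers
early.
"""

from gadock.analysis import vs_metrics
from gadock.fixtures import make_redocking_suite, make_toy_ligand
from gadock.search import dock, run_htvs

cx = make_redocking_suite(1, seed=11, rotor_counts=[2], ref_runs=0)[0]
library = [("binder", cx.ligand, True)]
for i in range(5):
    lig = make_toy_ligand(seed=80 + i, n_heavy=3, n_rotatable=0,
                          features=("hydrophobic",))
    library.append((f"decoy{i}", lig, False))

rows = []
for name, lig, active in library:
    res = dock(lig, cx.receptor, cx.cavity, n_runs=3, seed=[5, len(rows)])
    rows.append((name, res[0].breakdown.total, active))
    print(f"{name:8s} best score {res[0].breakdown.total:8.2f}")

met = vs_metrics(rows, fractions=(0.2,))
print(f"AUC {met.auc:.2f}  EF(20%) {met.ef[0.2]:.2f}  EFmax {met.ef_max:.2f}")
# AUC 1.0 means every decoy scored worse than the binder

ligs = [lig for _, lig, _ in library]
results, survivors = run_htvs(ligs, [(1, -10.0), (3, None)],
                              cx.receptor, cx.cavity, seed=5)
print("stage-1 survivors:", survivors[0],
      "(ligands whose 1-run score was at or below -10)")
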