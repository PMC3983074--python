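"""Score a pose and inspect the components of the total.

The total is a weighted sum of the intermolecular term (vdW + polar), the
ligand strain relative to its input conformation, the flexible-site term,
and restraint penalties.  At the constructed optimum the strain is 0 and
the intermolecular term dominates.
"""

from gadock.fixtures import make_redocking_suite
from gadock.scoring import score_pose

cx = make_redocking_suite(1, seed=11, rotor_counts=[2], ref_runs=0)[0]
bd = score_pose(cx.ligand, cx.receptor, cx.cavity)
print(f"S_total     {bd.total:8.2f}")
print(f"S_inter     {bd.inter:8.2f}   (vdW {bd.sub_terms['inter.vdw']:.2f}, "
      f"polar {bd.sub_terms['inter.polar']:.2f})")
print(f"S_intra     {bd.intra:8.2f}   (0 at the input conformation)")
print(f"S_site      {bd.site:8.2f}")
print(f"S_restraint {bd.restraint:8.2f}   (cavity containment)")
# negative polar values come from satisfied hydrogen bonds (about -8 per
# ideal neutral contact); the vdW term rewards snug shape complementarity
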