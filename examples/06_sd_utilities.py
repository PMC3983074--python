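"""Post-docking SD-file utilities: filter, sort, report, symmetry RMSD.

Docks one ligand, writes scored poses to an SD file, then demonstrates the
record utilities on the result.
"""

import tempfile
from pathlib import Path

from gadock.analysis import (filter_records, report_records, sort_records,
                             symmetry_rmsd)
from gadock.fixtures import make_redocking_suite
from gadock.io_sdf import parse_sdf_records, write_sdf
from gadock.search import dock

cx = make_redocking_suite(1, seed=11, rotor_counts=[1], ref_runs=0)[0]
results = dock(cx.ligand, cx.receptor, cx.cavity, n_runs=5, seed=2)

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "poses.sdf"
    write_sdf([(r.pose, r.breakdown) for r in results], path)
    records = parse_sdf_records(path)
    print(f"wrote and re-read {len(records)} scored poses")

    good = filter_records(records, "SCORE < -10")
    print(f"{len(good)} poses pass 'SCORE < -10'")

    ranked = sort_records(records, "SCORE", numeric=True)
    print("best two after sorting by SCORE:")
    print(report_records(ranked[:2], ["SCORE", "SCORE.INTER"]), end="")

    rmsd = symmetry_rmsd(records[0], records[-1])
    print(f"symmetry-corrected RMSD between best and worst pose: {rmsd:.2f} A")
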