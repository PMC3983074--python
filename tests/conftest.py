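"""Shared fixtures: small molecules generated at test time (no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

from gadock.io_sdf import parse_sdf, parse_sdf_records
from gadock.model import Molecule
from gadock.torsions import make_ligand


def smiles_to_sdf_text(smiles: str, seed: int = 7, name: str = "mol") -> str:
    """Embed a SMILES with RDKit and return a single V2000 SDF record."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        AllChem.EmbedMolecule(mol, params)
    mol.SetProp("_Name", name)
    return Chem.MolToMolBlock(mol) + "\n$$$$\n"


@pytest.fixture
def ligand_from_smiles(tmp_path):
    def build(smiles: str, seed: int = 7, name: str = "mol"):
        p = tmp_path / f"{name}.sdf"
        p.write_text(smiles_to_sdf_text(smiles, seed, name))
        return parse_sdf(p)[0]

    return build


def water_mol2_text() -> str:
    return """@<TRIPOS>MOLECULE
water
 3 2 1
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 O1    0.0000    0.0000    0.0000 O.3     1 HOH  -0.8340
      2 H1    0.9572    0.0000    0.0000 H       1 HOH   0.4170
      3 H2   -0.2400    0.9266    0.0000 H       1 HOH   0.4170
@<TRIPOS>BOND
     1     1     2 1
     2     1     3 1
"""


def serine_fragment_mol2_text() -> str:
    """Serine-like side chain: CA-CB-OG-HG with a terminal hydroxyl."""
    return """@<TRIPOS>MOLECULE
ser-fragment
 9 8 1
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 CA    0.0000    0.0000    0.0000 C.3     1 SER   0.0000
      2 CB    1.5200    0.0000    0.0000 C.3     1 SER   0.0000
      3 OG    2.0300    1.3400    0.0000 O.3     1 SER  -0.6500
      4 HG    3.0000    1.3200    0.0000 H       1 SER   0.4000
      5 HA1  -0.3600   -0.5100    0.8900 H       1 SER   0.0000
      6 HA2  -0.3600   -0.5100   -0.8900 H       1 SER   0.0000
      7 HA3  -0.3600    1.0200    0.0000 H       1 SER   0.0000
      8 HB1   1.8900   -0.5100    0.8900 H       1 SER   0.0000
      9 HB2   1.8900   -0.5100   -0.8900 H       1 SER   0.0000
@<TRIPOS>BOND
     1     1     2 1
     2     2     3 1
     3     3     4 1
     4     1     5 1
     5     1     6 1
     6     1     7 1
     7     2     8 1
     8     2     9 1
"""


@pytest.fixture
def water_mol2(tmp_path):
    p = tmp_path / "water.mol2"
    p.write_text(water_mol2_text())
    return p


@pytest.fixture
def serine_mol2(tmp_path):
    p = tmp_path / "ser.mol2"
    p.write_text(serine_fragment_mol2_text())
    return p


def simple_molecule(elements, coords, bonds, charges=None) -> Molecule:
    return Molecule(elements, np.asarray(coords, dtype=float), bonds,
                    formal_charges=charges)


# ----------------------------------------------------------------------
# shared (expensive) docking campaign, built once per session


@pytest.fixture(scope="session")
def redock_suite():
    from gadock.fixtures import make_redocking_suite

    return make_redocking_suite(20, seed=3)


@pytest.fixture(scope="session")
def redock_campaign(redock_suite):
    """Full 50-run docking campaign over the 20-system suite.

    Returns per-system dicts with the DockResult list (sorted by score) and
    the ligand/optimum for RMSD checks.
    """
    from gadock.search import dock

    out = []
    for cx in redock_suite:
        results = dock(cx.ligand, cx.receptor, cx.cavity, n_runs=50,
                       seed=[17, cx.metadata["index"]])
        out.append({"complex": cx, "results": results})
    return out
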