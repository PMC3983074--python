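"""Rotatable-torsion perception for ligands and receptors.

Ligands: every single, acyclic bond between two non-terminal heavy atoms is
rotatable, except amide C-N bonds and bonds whose rotation moves only apolar
hydrogens (methyl/CF3-type rotors); rotors that move a polar hydrogen (OH,
NH) are kept because they change the polar term.

Receptors: only torsions rotating a terminal hydroxyl or ammonium group
(optionally filtered to groups near the docking volume).
"""

from __future__ import annotations

import numpy as np

from .model import Dihedral, Ligand, Molecule, Receptor, _component_after_cut

__all__ = [
    "perceive_rotatable_dihedrals",
    "perceive_receptor_flexibility",
    "make_ligand",
]


def _ring_bonds(mol: Molecule) -> set[frozenset]:
    out = set()
    for ring in mol.rings:
        ring = set(ring)
        for i, j, _ in mol.bonds:
            if i in ring and j in ring:
                out.add(frozenset((i, j)))
    return out


def _is_amide(mol: Molecule, i: int, j: int) -> bool:
    """C-N single bond where the carbon carries a double-bonded O (or S)."""
    for c, nn in ((i, j), (j, i)):
        if mol.elements[c] == "C" and mol.elements[nn] == "N":
            for k in mol.neighbors(c):
                if k != nn and mol.elements[k] in ("O", "S") \
                        and (mol.bond_order(c, k) or 0) >= 2:
                    return True
    return False


def _build_dihedral(mol: Molecule, b: int, c: int) -> Dihedral:
    """Canonical dihedral for bond b-c, rotating the side containing c.

    The rotated side is chosen as the smaller component; reference atoms a
    (neighbour of b) and d (neighbour of c) prefer heavy atoms, lowest index
    first, for reproducibility.
    """
    side_c = _component_after_cut(mol, c, b)
    side_b = _component_after_cut(mol, b, c)
    if len(side_b) < len(side_c):
        b, c = c, b
        side_c = side_b

    def pick(center: int, exclude: int) -> int:
        cands = [k for k in mol.neighbors(center) if k != exclude]
        heavy = [k for k in cands if mol.elements[k] != "H"]
        return min(heavy) if heavy else min(cands)

    a = pick(b, c)
    d = pick(c, b)
    return Dihedral((a, b, c, d), frozenset(side_c))


def perceive_rotatable_dihedrals(mol: Molecule) -> list[Dihedral]:
    if mol.interaction_classes is None:
        from .atomtypes import assign_interaction_classes

        assign_interaction_classes(mol)
    ring_bonds = _ring_bonds(mol)
    out = []
    for i, j, order in sorted(mol.bonds):
        if order != 1 or frozenset((i, j)) in ring_bonds:
            continue
        if mol.elements[i] == "H" or mol.elements[j] == "H":
            continue
        deg_i = sum(1 for _ in mol.neighbors(i))
        deg_j = sum(1 for _ in mol.neighbors(j))
        if deg_i < 2 or deg_j < 2:
            continue
        if _is_amide(mol, i, j):
            continue
        dih = _build_dihedral(mol, i, j)
        moved = dih.rotated_set - {dih.atom_indices[2]}
        if all(mol.elements[k] == "H" for k in moved):
            # terminal rotor: keep only if it carries a polar hydrogen
            if not any(mol.interaction_classes[k] == "donor-H" for k in moved):
                continue
        out.append(dih)
    return out


def make_ligand(mol: Molecule) -> Ligand:
    from .atomtypes import assign_interaction_classes

    if mol.interaction_classes is None:
        assign_interaction_classes(mol)
    return Ligand(mol, perceive_rotatable_dihedrals(mol))


def perceive_receptor_flexibility(rec: Receptor, cavity=None, margin: float = 2.0,
                                  include_waters: bool = False) -> list[Dihedral]:
    """Terminal OH / NH3+ torsions, optionally within ``margin`` of a cavity.

    Water O-H bonds are excluded by default (receptor flexibility is limited
    to terminal hydroxyl/ammonium groups of residues); ``include_waters``
    re-enables them.
    """
    mol = rec.molecule
    if mol.interaction_classes is None:
        from .atomtypes import assign_interaction_classes

        assign_interaction_classes(mol)
    out = []
    for i, el in enumerate(mol.elements):
        nbrs = mol.neighbors(i)
        hs = [k for k in nbrs if mol.elements[k] == "H"]
        heavies = [k for k in nbrs if mol.elements[k] != "H"]
        group = None
        if el == "O" and len(hs) == 1 and len(heavies) == 1:
            group = "OH"
        elif el == "O" and len(hs) == 2 and len(heavies) == 0:
            if include_waters:
                group = "water"
            else:
                continue
        elif el == "N" and len(hs) == 3 and len(heavies) == 1 \
                and mol.formal_charges[i] > 0:
            group = "NH3+"
        if group is None or group == "water":
            continue
        y = heavies[0]
        y_heavies = [k for k in mol.neighbors(y) if mol.elements[k] != "H" and k != i]
        if not y_heavies:
            continue
        x = min(y_heavies)
        if cavity is not None:
            from .cavity import distance_to_cavity

            if distance_to_cavity(cavity, mol.coords[i]) > margin:
                continue
        rotated = frozenset({i, *hs})
        out.append(Dihedral((x, y, i, min(hs)), rotated))
    return out
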