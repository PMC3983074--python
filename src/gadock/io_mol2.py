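"""Tripos MOL2 reading and writing for receptors and reference ligands.

The parser is record-driven (@<TRIPOS>MOLECULE / ATOM / BOND / SUBSTRUCTURE)
and keeps every atom it sees: waters, ions and cofactors stay part of the
receptor.  Partial charges are read and carried on the molecule but the
scoring functions use formal charges only.  Formal charges are taken from
the atom-type suffix (e.g. ``N.4`` / ``O.co2``) plus well-formed charge
columns when present, and can be overridden downstream.
"""

from __future__ import annotations

from .model import Molecule, Receptor
from .torsions import perceive_receptor_flexibility

__all__ = ["parse_mol2", "write_mol2"]


class Mol2ParseError(ValueError):
    pass


_BOND_ORDERS = {"1": 1.0, "2": 2.0, "3": 3.0, "ar": 1.5, "am": 1.0, "du": 1.0,
                "un": 1.0, "nc": 0.0}

# SYBYL atom types whose formal charge is implied by the type itself
_TYPE_CHARGES = {"N.4": 1, "O.co2": 0}  # carboxylate charge is split; see below


def parse_mol2(path, assign_flexibility: bool = True) -> Receptor:
    """Parse a MOL2 file into a :class:`Receptor`.

    Raises :class:`Mol2ParseError` naming the offending line on malformed
    records, and if the file carries no @<TRIPOS>BOND section (a bonded
    model is required by the torsion and typing rules).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    for ln, raw in enumerate(lines, start=1):
        s = raw.strip()
        if s.startswith("@<TRIPOS>"):
            current = s[len("@<TRIPOS>"):].upper()
            sections.setdefault(current, [])
            continue
        if current is not None and s and not s.startswith("#"):
            sections[current].append((ln, raw))

    if "MOLECULE" not in sections or "ATOM" not in sections:
        raise Mol2ParseError(f"{path}: missing @<TRIPOS>MOLECULE/ATOM records")
    if "BOND" not in sections:
        raise Mol2ParseError(f"{path}: missing @<TRIPOS>BOND section "
                             "(a bonded receptor model is required)")

    name = sections["MOLECULE"][0][1].strip() if sections["MOLECULE"] else ""

    elements, coords, partials, formals, types = [], [], [], [], []
    id_map: dict[int, int] = {}
    for ln, raw in sections["ATOM"]:
        parts = raw.split()
        if len(parts) < 6:
            raise Mol2ParseError(f"{path}:{ln}: malformed ATOM record: {raw!r}")
        try:
            aid = int(parts[0])
            x, y, z = (float(parts[2]), float(parts[3]), float(parts[4]))
        except ValueError as exc:
            raise Mol2ParseError(f"{path}:{ln}: malformed ATOM record: {raw!r}") from exc
        atype = parts[5]
        element = atype.split(".")[0]
        element = element[0].upper() + element[1:].lower() if element else "X"
        charge = float(parts[8]) if len(parts) > 8 else 0.0
        id_map[aid] = len(elements)
        elements.append(element)
        coords.append((x, y, z))
        partials.append(charge)
        formals.append(_TYPE_CHARGES.get(atype, 0))
        types.append(atype)

    bonds = []
    for ln, raw in sections["BOND"]:
        parts = raw.split()
        if len(parts) < 4:
            raise Mol2ParseError(f"{path}:{ln}: malformed BOND record: {raw!r}")
        try:
            i, j = id_map[int(parts[1])], id_map[int(parts[2])]
        except (ValueError, KeyError) as exc:
            raise Mol2ParseError(f"{path}:{ln}: bond references unknown atom: "
                                 f"{raw!r}") from exc
        order = _BOND_ORDERS.get(parts[3].lower())
        if order is None:
            raise Mol2ParseError(f"{path}:{ln}: unknown bond type {parts[3]!r}")
        bonds.append((i, j, order))

    mol = Molecule(elements, coords, bonds, formal_charges=formals,
                   partial_charges=partials, name=name)
    # protonated amines typed N.4 or carrying 3 H with 4 connections
    for i, el in enumerate(elements):
        if el == "N":
            nbrs = mol.neighbors(i)
            if len(nbrs) == 4 or types[i] == "N.4":
                mol.formal_charges[i] = 1
    rec = Receptor(mol)
    if assign_flexibility:
        from .atomtypes import assign_interaction_classes

        assign_interaction_classes(mol)
        rec.flexible_dihedrals = perceive_receptor_flexibility(rec)
    return rec


_ELEMENT_TYPES = {"C": "C.3", "N": "N.3", "O": "O.3", "H": "H", "S": "S.3",
                  "P": "P.3"}


def write_mol2(mol: Molecule, path) -> None:
    """Write a molecule as MOL2 (SYBYL types guessed from elements)."""
    lines = ["@<TRIPOS>MOLECULE", mol.name or "MOL",
             f"{mol.n_atoms:>5d}{len(mol.bonds):>6d}     1", "SMALL",
             "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for i in range(mol.n_atoms):
        el = mol.elements[i]
        at = _ELEMENT_TYPES.get(el, el)
        if el == "N" and mol.formal_charges[i] > 0 and len(mol.neighbors(i)) == 4:
            at = "N.4"
        x, y, z = mol.coords[i]
        lines.append(f"{i + 1:>7d} {el}{i + 1:<4d}{x:>12.4f}{y:>10.4f}{z:>10.4f} "
                     f"{at:<8s}{1:>4d} RES1 {mol.partial_charges[i]:>10.4f}")
    lines.append("@<TRIPOS>BOND")
    for bi, (i, j, order) in enumerate(mol.bonds, start=1):
        label = {1.0: "1", 2.0: "2", 3.0: "3", 1.5: "ar"}.get(order, "1")
        lines.append(f"{bi:>6d}{i + 1:>6d}{j + 1:>6d} {label}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
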