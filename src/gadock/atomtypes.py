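"""Interaction-class assignment from the molecular graph + formal charges.

The empirical polar term, the desolvation weights and the pharmacophore
feature detector all key off these classes, so the assignment must be a pure
function of the bond graph and formal charges (never of coordinates).

The rule table (which elements are metals, which heteroatoms accept, the
polar-hydrogen definition) lives in ``data/params.yaml`` under
``interaction_rules`` so users can extend it without touching code.
"""

from __future__ import annotations

import warnings

from .model import HALOGENS, METALS, Molecule
from .params import load_param_table

__all__ = ["assign_interaction_classes"]


def _rules():
    return load_param_table()["interaction_rules"]


def assign_interaction_classes(mol: Molecule) -> Molecule:
    """Label every atom with exactly one interaction class (in place).

    Classes: ``donor-H`` (H on N/O/S), ``acceptor`` (lone-pair N/O/S),
    ``polar-H carrier`` (heavy atom bearing a polar H that is not itself an
    acceptor, e.g. tetra-coordinated N+), ``apolar`` (C, halogens, H on C),
    ``metal`` and ``other``.  Charge centres are carried as separate boolean
    flags: a quaternary/protonated nitrogen is a positive centre; atoms with
    negative formal charge — and both oxygens of a carboxylate /
    (thio)phosphate-style group, where the charge is delocalised — are
    negative centres.
    """
    rules = _rules()
    metals = set(rules.get("metals", [])) or METALS
    donor_roots = set(rules.get("polar_h_roots", ["N", "O", "S"]))
    n = mol.n_atoms
    classes = ["other"] * n
    pos = [False] * n
    neg = [False] * n
    nbrs = [mol.neighbors(i) for i in range(n)]

    for i, el in enumerate(mol.elements):
        fc = int(mol.formal_charges[i])
        if el in metals:
            classes[i] = "metal"
            pos[i] = fc > 0
            continue
        if el == "H":
            root = nbrs[i][0] if nbrs[i] else None
            if root is not None and mol.elements[root] in donor_roots:
                classes[i] = "donor-H"
            else:
                classes[i] = "apolar"
            continue
        if el == "C" or el in HALOGENS:
            classes[i] = "apolar"
            neg[i] = fc < 0
            pos[i] = fc > 0
            continue
        has_h = any(mol.elements[j] == "H" for j in nbrs[i])
        if el == "O":
            classes[i] = "acceptor"
            neg[i] = fc < 0
        elif el == "N":
            if fc > 0:
                pos[i] = True
                classes[i] = "polar-H carrier" if has_h else "other"
            elif has_h:
                classes[i] = "polar-H carrier"
            else:
                classes[i] = "acceptor"
        elif el == "S":
            classes[i] = "polar-H carrier" if has_h else "acceptor"
            neg[i] = fc < 0
        elif el == "P":
            classes[i] = "other"
            pos[i] = fc > 0
        else:
            warnings.warn(f"unknown element {el!r}: interaction class 'other'")
            classes[i] = "other"

    _flag_delocalised_anions(mol, neg, nbrs)
    mol.interaction_classes = classes
    import numpy as np

    mol.positive_flags = np.array(pos)
    mol.negative_flags = np.array(neg)
    return mol


def _flag_delocalised_anions(mol: Molecule, neg: list[bool], nbrs) -> None:
    """Carboxylate-style groups: X(-O)(-O^-) -> both oxygens negative."""
    for c, el in enumerate(mol.elements):
        if el not in ("C", "P", "S"):
            continue
        oxygens = [j for j in nbrs[c] if mol.elements[j] == "O"
                   and len(nbrs[j]) == 1]
        if len(oxygens) >= 2 and any(neg[j] for j in oxygens):
            for j in oxygens:
                neg[j] = True
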