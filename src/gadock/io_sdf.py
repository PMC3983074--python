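"""MDL SDF (V2000) reading and writing.

Records are split and their SD data fields handled directly so the
parse -> write -> parse round trip preserves field text byte-identically;
RDKit is used per record for aromaticity/ring perception (and, elsewhere,
SMARTS matching and automorphisms).  Formal charges come from ``M  CHG``
property lines (charges in atom-block column 36-39 are ignored, as modern
writers do).
"""

from __future__ import annotations

import warnings

from .model import Ligand, Molecule
from .torsions import make_ligand

__all__ = ["parse_sdf", "parse_sdf_records", "write_sdf", "molecule_to_molblock"]


class SdfParseError(ValueError):
    pass


def _split_records(text: str) -> list[list[str]]:
    records, cur = [], []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append(cur)
            cur = []
        else:
            cur.append(line)
    if any(l.strip() for l in cur):
        records.append(cur)
    return records


def _parse_record(lines: list[str], idx: int) -> Molecule:
    if len(lines) < 4:
        raise SdfParseError(f"record {idx}: truncated header")
    name = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise SdfParseError(f"record {idx}: malformed counts line {counts!r}") from exc
    atom_lines = lines[4:4 + n_atoms]
    bond_lines = lines[4 + n_atoms:4 + n_atoms + n_bonds]
    if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise SdfParseError(f"record {idx}: counts line declares {n_atoms} atoms/"
                            f"{n_bonds} bonds but the connection table is shorter")
    elements, coords = [], []
    for ln in atom_lines:
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            el = ln[31:34].strip()
            if not el:
                raise ValueError
        except (ValueError, IndexError) as exc:
            raise SdfParseError(f"record {idx}: malformed atom line {ln!r}") from exc
        elements.append(el)
        coords.append((x, y, z))
    bonds = []
    for ln in bond_lines:
        try:
            i, j, o = int(ln[0:3]) - 1, int(ln[3:6]) - 1, int(ln[6:9])
        except (ValueError, IndexError) as exc:
            raise SdfParseError(f"record {idx}: malformed bond line {ln!r}") from exc
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise SdfParseError(f"record {idx}: bond endpoint out of range in {ln!r}")
        bonds.append((i, j, 1.5 if o == 4 else float(o)))

    charges = [0] * n_atoms
    k = 4 + n_atoms + n_bonds
    while k < len(lines):
        ln = lines[k]
        if ln.startswith("M  END"):
            k += 1
            break
        if ln.startswith("M  CHG"):
            parts = ln.split()
            cnt = int(parts[2])
            for c in range(cnt):
                charges[int(parts[3 + 2 * c]) - 1] = int(parts[4 + 2 * c])
        k += 1

    # SD data fields: "> <NAME>" header, value lines, blank separator
    sd_fields: dict[str, str] = {}
    while k < len(lines):
        ln = lines[k]
        if ln.startswith(">"):
            fname = ln[ln.find("<") + 1:ln.find(">", ln.find("<"))] \
                if "<" in ln else ln[1:].strip()
            vals = []
            k += 1
            while k < len(lines) and lines[k].strip() != "":
                vals.append(lines[k])
                k += 1
            sd_fields[fname] = "\n".join(vals)
        k += 1

    mol = Molecule(elements, coords, bonds, formal_charges=charges,
                   name=name, sd_fields=sd_fields)
    _perceive_with_rdkit(mol, lines[:4 + n_atoms + n_bonds] + ["M  END"])
    return mol


def _perceive_with_rdkit(mol: Molecule, ctab_lines: list[str]) -> None:
    """Aromaticity + SSSR from RDKit; falls back to graph rings on failure."""
    try:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        block = "\n".join(ctab_lines) + "\n"
        rd = Chem.MolFromMolBlock(block, sanitize=True, removeHs=False)
        if rd is None:
            rd = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
            if rd is not None:
                Chem.GetSymmSSSR(rd)
        if rd is None or rd.GetNumAtoms() != mol.n_atoms:
            return
        arom = {tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
                for b in rd.GetBonds() if b.GetIsAromatic()}
        mol.bonds = [(i, j, 1.5 if tuple(sorted((i, j))) in arom else o)
                     for i, j, o in mol.bonds]
        ri = rd.GetRingInfo()
        mol._rings = [frozenset(r) for r in ri.AtomRings()]
    except Exception:  # pragma: no cover - perception is best-effort
        return


def parse_sdf_records(path) -> list[Molecule]:
    """All records of an SD file as molecules (no torsion perception)."""
    with open(path) as fh:
        text = fh.read()
    records = _split_records(text)
    if not records:
        warnings.warn(f"{path}: empty SD file")
        return []
    return [_parse_record(rec, i) for i, rec in enumerate(records)]


def parse_sdf(path) -> list[Ligand]:
    """One :class:`Ligand` per V2000 record, with typing + rotors perceived."""
    return [make_ligand(m) for m in parse_sdf_records(path)]


def molecule_to_molblock(mol: Molecule) -> str:
    lines = [mol.name, "  gadock            3D", "",
             f"{mol.n_atoms:>3d}{len(mol.bonds):>3d}  0  0  0  0  0  0  0  0999 V2000"]
    for i in range(mol.n_atoms):
        x, y, z = mol.coords[i]
        lines.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {mol.elements[i]:<3s}"
                     " 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, o in mol.bonds:
        order = 4 if o == 1.5 else int(o)
        lines.append(f"{i + 1:>3d}{j + 1:>3d}{order:>3d}  0")
    chg = [(i + 1, int(c)) for i, c in enumerate(mol.formal_charges) if c]
    for start in range(0, len(chg), 8):
        chunk = chg[start:start + 8]
        lines.append("M  CHG" + f"{len(chunk):>3d}"
                     + "".join(f"{a:>4d}{c:>4d}" for a, c in chunk))
    lines.append("M  END")
    return "\n".join(lines)


SCORE_FIELDS = ("SCORE", "SCORE.INTER", "SCORE.INTRA", "SCORE.SITE", "SCORE.RESTR")


def write_sdf(poses, path) -> None:
    """Write ``(Ligand, ScoreBreakdown | None)`` pairs as an SD file.

    Original SD data fields are preserved; score components are appended as
    SCORE, SCORE.INTER, SCORE.INTRA, SCORE.SITE and SCORE.RESTR fields.
    An empty pose list yields a valid empty file.
    """
    chunks = []
    for lig, breakdown in poses:
        mol = lig.molecule if isinstance(lig, Ligand) else lig
        fields = dict(mol.sd_fields)
        if breakdown is not None:
            fields["SCORE"] = f"{breakdown.total:.4f}"
            fields["SCORE.INTER"] = f"{breakdown.inter:.4f}"
            fields["SCORE.INTRA"] = f"{breakdown.intra:.4f}"
            fields["SCORE.SITE"] = f"{breakdown.site:.4f}"
            fields["SCORE.RESTR"] = f"{breakdown.restraint:.4f}"
        body = molecule_to_molblock(mol)
        for k, v in fields.items():
            body += f"\n>  <{k}>\n{v}\n"
        chunks.append(body + "\n$$$$\n")
    with open(path, "w") as fh:
        fh.write("".join(chunks))
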