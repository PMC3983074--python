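"""Post-docking analysis: symmetry-aware RMSD, SD-record utilities and
virtual-screening enrichment metrics.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Ligand, Molecule

__all__ = [
    "symmetry_rmsd",
    "naive_rmsd",
    "filter_records",
    "sort_records",
    "report_records",
    "vs_metrics",
    "VSMetrics",
]


# ----------------------------------------------------------------------
# symmetry-corrected RMSD


def _as_mol(x) -> Molecule:
    return x.molecule if isinstance(x, Ligand) else x


def _largest_fragment(mol: Molecule) -> list[int]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    return sorted(comps[0]) if comps else []


def _automorphisms(mol: Molecule, heavy_only: bool, cap: int):
    """Element- and bond-order-preserving graph automorphisms via RDKit
    self substructure matching."""
    from rdkit import Chem

    from .io_sdf import molecule_to_molblock

    rd = Chem.MolFromMolBlock(molecule_to_molblock(mol), sanitize=False,
                              removeHs=False)
    Chem.GetSymmSSSR(rd)
    if heavy_only:
        rd = Chem.RWMol(rd)
        for i in sorted((a.GetIdx() for a in rd.GetAtoms()
                         if a.GetSymbol() == "H"), reverse=True):
            rd.RemoveAtom(i)
    matches = rd.GetSubstructMatches(rd, uniquify=False, maxMatches=cap,
                                     useChirality=False)
    if len(matches) >= cap:
        warnings.warn(f"automorphism enumeration capped at {cap} mappings; "
                      "the RMSD may be an upper bound")
    return matches


def naive_rmsd(ref, pose, heavy_only: bool = True) -> float:
    """Index-matched RMSD in the docking frame (no re-superposition)."""
    rm, pm = _as_mol(ref), _as_mol(pose)
    mask = rm.heavy_mask if heavy_only else np.ones(rm.n_atoms, bool)
    d = rm.coords[mask] - pm.coords[mask]
    return float(np.sqrt(np.mean((d ** 2).sum(axis=1))))


def symmetry_rmsd(ref, pose, heavy_only: bool = True,
                  max_mappings: int = 100000) -> float:
    """Minimum RMSD over all topological automorphisms of the ligand graph.

    Coordinates are compared in the docking frame (no re-superposition),
    matching reference-versus-docked-pose semantics.  Multi-fragment
    records are compared on their largest fragment.  Raises ``ValueError``
    when the two molecular graphs differ.
    """
    rm, pm = _as_mol(ref), _as_mol(pose)
    frag_r, frag_p = _largest_fragment(rm), _largest_fragment(pm)
    if [rm.elements[i] for i in frag_r] != [pm.elements[i] for i in frag_p] \
            or len(rm.bonds) != len(pm.bonds):
        raise ValueError("reference and pose have different molecular graphs")
    sub_r = _subset(rm, frag_r)
    sub_p = _subset(pm, frag_p)
    mask = sub_r.heavy_mask if heavy_only else np.ones(sub_r.n_atoms, bool)
    keep = np.nonzero(mask)[0]
    # map heavy-only automorphism indices back to full-fragment indices
    heavy_of = {h: i for h, i in enumerate(keep)}
    ref_xyz = sub_r.coords[keep]
    best = math.inf
    for mapping in _automorphisms(sub_r, heavy_only, max_mappings):
        pose_xyz = sub_p.coords[[heavy_of[m] for m in mapping]] \
            if heavy_only else sub_p.coords[list(mapping)]
        d = ref_xyz - pose_xyz
        r = float(np.sqrt(np.mean((d ** 2).sum(axis=1))))
        best = min(best, r)
    return best


def _subset(mol: Molecule, idx: list[int]) -> Molecule:
    pos = {a: k for k, a in enumerate(idx)}
    bonds = [(pos[i], pos[j], o) for i, j, o in mol.bonds
             if i in pos and j in pos]
    return Molecule([mol.elements[i] for i in idx], mol.coords[idx], bonds,
                    [mol.formal_charges[i] for i in idx])


# ----------------------------------------------------------------------
# SD-record filter / sort / report


_TOKEN = re.compile(r"""\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op><=|>=|==|!=|<|>|=)
    |(?P<and>[aA][nN][dD]\b)|(?P<or>[oO][rR]\b)|(?P<not>[nN][oO][tT]\b)
    |(?P<str>'[^']*'|"[^"]*")|(?P<word>[^\s()<>=!]+))""", re.X)


def _tokenize(expr: str):
    out, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m or m.end() == pos:
            raise ValueError(f"malformed filter expression near {expr[pos:]!r}")
        pos = m.end()
        for kind in ("lpar", "rpar", "op", "and", "or", "not", "str", "word"):
            if m.group(kind) is not None:
                val = m.group(kind)
                if kind == "str":
                    val = val[1:-1]
                out.append((kind if kind not in ("and", "or", "not") else kind,
                            val))
                break
    return out


class _MissingField(Exception):
    pass


def _compile_expression(expr: str):
    """Recursive-descent parser for ``FIELD <op> value`` comparisons joined
    by and/or/not with parentheses.  Returns a predicate over a field dict."""
    tokens = _tokenize(expr)
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else (None, None)

    def eat(kind=None):
        k, v = peek()
        if kind is not None and k != kind:
            raise ValueError(f"malformed filter expression: expected {kind}, "
                             f"got {v!r}")
        pos[0] += 1
        return k, v

    def parse_or():
        node = parse_and()
        while peek()[0] == "or":
            eat()
            rhs = parse_and()
            node = (lambda a, b: lambda f: a(f) or b(f))(node, rhs)
        return node

    def parse_and():
        node = parse_not()
        while peek()[0] == "and":
            eat()
            rhs = parse_not()
            node = (lambda a, b: lambda f: a(f) and b(f))(node, rhs)
        return node

    def parse_not():
        if peek()[0] == "not":
            eat()
            inner = parse_not()
            return lambda f: not inner(f)
        return parse_atom()

    def parse_atom():
        k, v = peek()
        if k == "lpar":
            eat()
            node = parse_or()
            eat("rpar")
            return node
        _, lhs = eat()
        opk, op = eat("op")
        _, rhs = eat()
        return _comparison(lhs, op, rhs)

    pred = parse_or()
    if pos[0] != len(tokens):
        raise ValueError("malformed filter expression: trailing tokens")

    def safe(fields):
        try:
            return pred(fields)
        except _MissingField:
            return None
    return safe


def _resolve(term: str, fields: dict):
    if term in fields:
        return fields[term]
    if term.startswith("$") and term[1:] in fields:
        return fields[term[1:]]
    try:
        float(term)
        return term
    except ValueError:
        pass
    # bare word that is not a field of this record
    if term.startswith("$") or term.isupper() or "." in term:
        raise _MissingField(term)
    return term


def _comparison(lhs: str, op: str, rhs: str):
    def cmp(fields):
        a = _resolve(lhs, fields)
        b = _resolve(rhs, fields)
        try:
            a2, b2 = float(a), float(b)
        except (TypeError, ValueError):
            a2, b2 = str(a), str(b)
        if op in ("=", "=="):
            return a2 == b2
        if op == "!=":
            return a2 != b2
        if op == "<":
            return a2 < b2
        if op == "<=":
            return a2 <= b2
        if op == ">":
            return a2 > b2
        return a2 >= b2
    return cmp


def _record_fields(rec) -> dict:
    mol = _as_mol(rec) if isinstance(rec, (Ligand, Molecule)) else None
    if mol is not None:
        f = dict(mol.sd_fields)
        f.setdefault("_TITLE", mol.name)
        return f
    return dict(rec)


def filter_records(records, expression: str):
    """Order-preserving subset of records where the expression is true.

    Comparisons are numeric when both sides parse as numbers, else
    lexicographic.  Records missing a referenced field are excluded with a
    warning.  The expression is compiled (and validated) before any record
    is touched.
    """
    pred = _compile_expression(expression)
    out = []
    for rec in records:
        res = pred(_record_fields(rec))
        if res is None:
            warnings.warn("record skipped: filter references a missing field")
            continue
        if res:
            out.append(rec)
    return out


def sort_records(records, fld: str, numeric: bool = True,
                 descending: bool = False):
    """Stable sort by an SD data field; records missing the field sort last."""
    def key(rec):
        f = _record_fields(rec)
        if fld not in f:
            return (1, 0.0 if numeric else "")
        v = f[fld]
        if numeric:
            try:
                return (0, float(v))
            except ValueError:
                return (1, 0.0)
        return (0, str(v))

    return sorted(records, key=key, reverse=descending)


def report_records(records, fields, dialect: str = "csv") -> str:
    """Tabular report of SD data fields (RFC-4180 CSV or tab-delimited)."""
    import csv

    buf = io.StringIO()
    if dialect == "csv":
        w = csv.writer(buf, lineterminator="\n")
    else:
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(fields)
    for rec in records:
        f = _record_fields(rec)
        w.writerow([f.get(name, "") for name in fields])
    return buf.getvalue()


# ----------------------------------------------------------------------
# virtual-screening metrics


@dataclass
class VSMetrics:
    auc: float
    log_auc: float
    ef: dict
    ef_max: float
    roc_points: list = field(default_factory=list)


LOGAUC_FLOOR = 1e-3  # lower limit of the logarithmic FPR axis
#: logAUC of a random ranking under this convention
LOGAUC_RANDOM = (1.0 - LOGAUC_FLOOR) / math.log(10) / (-math.log10(LOGAUC_FLOOR))


def vs_metrics(scores, fractions=(0.01, 0.2), lower_is_better: bool = True) -> VSMetrics:
    """Enrichment metrics for a scored library.

    ``scores`` is a sequence of ``(id, score, is_active)``.  The ROC is
    swept over score thresholds with tied scores processed as a block
    (diagonal segments), which makes the AUC equal the Mann-Whitney
    statistic.  logAUC is the area under TPR vs log10(FPR) for FPR in
    [1e-3, 1], normalised so a random ranking scores ~0.1446.  EF(x) =
    (actives in the top x fraction / total actives) / x, with the selection
    size rounded to the nearest compound; EFmax is the maximum of EF over
    all top-k prefixes.
    """
    rows = [(str(i), float(s), bool(a)) for i, s, a in scores]
    n_act = sum(1 for r in rows if r[2])
    n_dec = len(rows) - n_act
    if n_act == 0 or n_dec == 0:
        raise ValueError("need at least one active and one decoy")
    sign = 1.0 if lower_is_better else -1.0
    rows.sort(key=lambda r: sign * r[1])

    # tie-blocked ROC sweep
    roc = [(0.0, 0.0)]
    tp = fp = 0
    k = 0
    while k < len(rows):
        j = k
        while j < len(rows) and rows[j][1] == rows[k][1]:
            j += 1
        tp += sum(1 for r in rows[k:j] if r[2])
        fp += (j - k) - sum(1 for r in rows[k:j] if r[2])
        roc.append((fp / n_dec, tp / n_act))
        k = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(roc[:-1], roc[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0

    log_auc = _log_auc(roc)

    ef = {}
    for x in fractions:
        n_sel = max(1, int(round(x * len(rows))))
        hits = sum(1 for r in rows[:n_sel] if r[2])
        ef[x] = (hits / n_act) / x
    ef_max = 0.0
    hits = 0
    for k, r in enumerate(rows, start=1):
        if r[2]:
            hits += 1
        ef_max = max(ef_max, (hits / n_act) / (k / len(rows)))
    return VSMetrics(auc, log_auc, ef, ef_max, roc)


def _log_auc(roc) -> float:
    """Area under TPR vs log10(FPR), FPR in [floor, 1], normalised by the
    width of the log axis."""
    lam = LOGAUC_FLOOR
    xs = np.array([p[0] for p in roc])
    ys = np.array([p[1] for p in roc])
    grid = np.concatenate([[lam], np.logspace(math.log10(lam), 0, 512)[1:]])
    tpr = np.interp(grid, xs, ys)
    area = np.trapezoid(tpr, np.log10(grid))
    return float(area / -math.log10(lam))
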