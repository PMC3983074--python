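"""Bias terms: pharmacophore spheres, tethered template, cavity containment
and NMR-style distance restraints.

Pharmacophore and distance restraints are soft quadratic penalties added to
the total score; tethering is enforced absolutely during pose generation
(the search restricts randomisation/mutation of the tethered degrees of
freedom), with :func:`tether_violation` available to verify emitted poses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Ligand, Molecule, Receptor

__all__ = [
    "FEATURE_TYPES",
    "PharmacophoreRestraint",
    "TetherSpec",
    "DistanceRestraint",
    "RestraintSet",
    "detect_features",
    "pharmacophore_penalty",
    "screen_ligand_features",
    "match_and_replicate",
    "prealign",
    "tether_violation",
    "cavity_penalty",
    "cavity_penalty_coords",
    "nmr_distance_penalty",
    "restraint_score",
    "parse_restraint_file",
]

FEATURE_TYPES = (
    "neutral HBA",
    "neutral HBD",
    "hydrophobic",
    "hydrophobic aliphatic",
    "hydrophobic aromatic",
    "negative",
    "positive",
    "any heavy atom",
)


@dataclass
class PharmacophoreRestraint:
    feature_type: str
    center: np.ndarray
    radius: float
    mandatory: bool = True
    weight: float = 1.0

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.radius <= 0:
            raise ValueError("tolerance sphere radius must be positive")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class TetherSpec:
    smarts: str
    reference_coords: np.ndarray
    trans_tol: float = 0.1   # Angstrom
    rot_tol: float = 1.0     # degrees
    #: explicit ligand-atom mapping (e.g. from an annotated SD field);
    #: when None the first SMARTS match is used
    mapping: tuple | None = None

    def __post_init__(self):
        if self.trans_tol < 0 or self.rot_tol < 0:
            raise ValueError("tether tolerances must be non-negative")
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.mapping is not None:
            self.mapping = tuple(int(i) for i in self.mapping)


@dataclass
class DistanceRestraint:
    ligand_atoms: list          # atom index list
    receptor_atoms: list
    bound: float                # Angstrom
    weight: float = 1.0
    lower_bound: bool = False   # default NOE-style upper bound

    def __post_init__(self):
        if self.bound <= 0:
            raise ValueError("distance bound must be positive")


@dataclass
class RestraintSet:
    pharmacophores: list = field(default_factory=list)
    n_opt: int = 0
    tether: TetherSpec | None = None
    distance_restraints: list = field(default_factory=list)
    pharmacophore_weight: float = 1.0

    def __post_init__(self):
        n_optional = sum(1 for p in self.pharmacophores if not p.mandatory)
        if not (0 <= self.n_opt <= n_optional):
            raise ValueError(f"n_opt must be in [0, {n_optional}]")


# ----------------------------------------------------------------------
# feature detection


def feature_index_map(mol: Molecule) -> dict:
    """Atom-index groups per feature type (coordinate-independent).

    Each entry is a list of index tuples; a feature's position is the mean
    of its atoms' coordinates (single atoms for atom-centred features,
    ring-atom tuples for aromatic centroids).
    """
    if mol.interaction_classes is None:
        from .atomtypes import assign_interaction_classes

        assign_interaction_classes(mol)
    idx = {ft: [] for ft in FEATURE_TYPES}
    aromatic_atoms = set()
    for ring in mol.rings:
        ring = sorted(ring)
        orders = [mol.bond_order(i, j) for i in ring for j in ring
                  if i < j and mol.bond_order(i, j) is not None]
        if orders and all(o == 1.5 for o in orders):
            idx["hydrophobic aromatic"].append(tuple(ring))
            aromatic_atoms.update(ring)
    for i in range(mol.n_atoms):
        if mol.elements[i] == "H":
            continue
        idx["any heavy atom"].append((i,))
        cls = mol.interaction_classes[i]
        if cls == "acceptor" and not mol.negative_flags[i]:
            idx["neutral HBA"].append((i,))
        if mol.negative_flags[i]:
            idx["negative"].append((i,))
        if mol.positive_flags[i]:
            idx["positive"].append((i,))
        if cls in ("acceptor", "polar-H carrier") and not mol.positive_flags[i]:
            if any(mol.elements[j] == "H"
                   and mol.interaction_classes[j] == "donor-H"
                   for j in mol.neighbors(i)):
                idx["neutral HBD"].append((i,))
        if cls == "apolar":
            idx["hydrophobic"].append((i,))
            if i not in aromatic_atoms:
                idx["hydrophobic aliphatic"].append((i,))
    return idx


def features_from_indices(coords, index_map: dict) -> dict:
    return {ft: np.array([coords[list(g)].mean(axis=0) for g in groups])
            .reshape(-1, 3) for ft, groups in index_map.items()}


def detect_features(lig: Ligand) -> dict:
    """Positions of the eight pharmacophore feature types.

    Atom-centred features use atom positions; aromatic rings additionally
    contribute their centroid as a "hydrophobic aromatic" feature.  The
    mapping is deterministic given the molecular graph.
    """
    mol = lig.molecule if isinstance(lig, Ligand) else lig
    return features_from_indices(mol.coords, feature_index_map(mol))


def pharmacophore_penalty(features: dict, rs: RestraintSet) -> float:
    """Sum of mandatory penalties plus the n_opt smallest optional penalties.

    Per restraint: d = max(0, |nearest matching feature - center| - radius);
    penalty = W * d^2 (0 when a feature sits inside the tolerance sphere).
    A required feature type with no ligand feature scores +inf (ligands are
    expected to have been screened out beforehand).
    """
    mand, opt = 0.0, []
    for r in rs.pharmacophores:
        pts = features.get(r.feature_type)
        if pts is None or len(pts) == 0:
            warnings.warn(f"no ligand feature of type {r.feature_type!r}; "
                          "pose penalised as infeasible")
            pen = math.inf
        else:
            d = np.linalg.norm(pts - r.center, axis=1).min()
            pen = r.weight * rs.pharmacophore_weight * max(0.0, d - r.radius) ** 2
        if r.mandatory:
            mand += pen
        else:
            opt.append(pen)
    opt.sort()
    return float(mand + sum(opt[:rs.n_opt]))


def screen_ligand_features(lig: Ligand, rs: RestraintSet) -> bool:
    """True iff the ligand can in principle satisfy the restraint set.

    Needs, for every feature type, at least as many ligand features as
    mandatory restraints of that type, and in the best case enough features
    across types to satisfy n_opt optional restraints.
    """
    feats = detect_features(lig)
    counts = {ft: len(feats[ft]) for ft in FEATURE_TYPES}
    satisfiable_opt = 0
    need = {}
    for r in rs.pharmacophores:
        if r.mandatory:
            need[r.feature_type] = need.get(r.feature_type, 0) + 1
        elif counts[r.feature_type] >= 1:
            satisfiable_opt += 1
    for ft, n in need.items():
        if counts[ft] < n:
            return False
    return satisfiable_opt >= rs.n_opt


# ----------------------------------------------------------------------
# tethered template


def _rdkit_mol(mol: Molecule):
    from rdkit import Chem

    from .io_sdf import molecule_to_molblock

    rd = Chem.MolFromMolBlock(molecule_to_molblock(mol), sanitize=True,
                              removeHs=False)
    if rd is None:
        rd = Chem.MolFromMolBlock(molecule_to_molblock(mol), sanitize=False,
                                  removeHs=False)
    return rd


def match_and_replicate(ligands, spec: TetherSpec, log=None):
    """One (prealigned ligand, atom mapping) entry per distinct match.

    Matches are enumerated without uniquification, each is prealigned onto
    the reference coordinates, and matches whose aligned whole-molecule
    geometries are indistinguishable (symmetry-corrected heavy-atom RMSD
    below 0.15 A) are collapsed: alignments related by a molecular
    automorphism place identical atoms at identical positions and would
    dock identically.  Non-matching ligands are dropped (logged).
    """
    from rdkit import Chem

    query = Chem.MolFromSmarts(spec.smarts)
    if query is None:
        raise ValueError(f"invalid SMARTS query: {spec.smarts!r}")
    out = []
    for lig in ligands:
        rd = _rdkit_mol(lig.molecule)
        if rd is None:
            if log is not None:
                log.append((lig.molecule.name, "rdkit-parse-failure"))
            continue
        from .analysis import symmetry_rmsd

        matches = rd.GetSubstructMatches(query, uniquify=False, maxMatches=10000)
        kept = []
        for mapping in matches:
            try:
                aligned = prealign(lig, mapping, spec)
            except ValueError:
                continue
            dup = any(symmetry_rmsd(aligned, prev) < 0.15 for prev, _ in kept)
            if not dup:
                kept.append((aligned, tuple(mapping)))
        if not kept and log is not None:
            log.append((lig.molecule.name, "no-substructure-match"))
        out.extend(kept)
    return out


def prealign(lig: Ligand, mapping, spec: TetherSpec) -> Ligand:
    """Kabsch superposition of the matched atoms onto the reference coords,
    applied to the whole molecule."""
    mapping = list(mapping)
    if len(mapping) != len(spec.reference_coords):
        raise ValueError("mapping length does not match reference coordinates")
    mob = lig.molecule.coords[mapping]
    ref = spec.reference_coords
    if len(mapping) < 3 or _collinear(ref):
        raise ValueError("tether orientation under-determined: need >= 3 "
                         "non-collinear matched atoms")
    R, t = _kabsch(mob, ref)
    new = lig.molecule.coords @ R.T + t
    return lig.with_coords(new)


def _collinear(pts, tol=1e-6) -> bool:
    pts = np.asarray(pts, dtype=float)
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] < tol


def _kabsch(mob, ref):
    """Least-squares rigid superposition: returns (R, t) with ref ~ mob@R.T + t."""
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    H = (mob - cm).T @ (ref - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - cm @ R.T
    return R, t


def tether_violation(pose: Ligand, spec: TetherSpec, mapping):
    """(trans_dev in A, rot_dev in degrees) of the tethered substructure.

    trans_dev is the displacement of the matched-atom centroid from the
    reference centroid; rot_dev is the angle of the optimal rotation
    between the centred matched atoms and the centred reference (the
    relative rotation of the substructure principal axes).
    """
    sub = pose.molecule.coords[list(mapping)]
    ref = spec.reference_coords
    trans_dev = float(np.linalg.norm(sub.mean(axis=0) - ref.mean(axis=0)))
    R, _ = _kabsch(ref, sub)
    cos_ang = (np.trace(R) - 1.0) / 2.0
    rot_dev = math.degrees(math.acos(min(1.0, max(-1.0, cos_ang))))
    return trans_dev, rot_dev


# ----------------------------------------------------------------------
# cavity containment + distance restraints


def cavity_penalty_coords(heavy_coords, grid, weight: float = 1.0) -> float:
    """W * sum over heavy atoms of squared distance to the nearest cavity
    grid point (zero for atoms within the docking volume)."""
    if len(heavy_coords) == 0:
        return 0.0
    from ._kernels import cavity_sq_dist_sum_lattice

    return float(weight * cavity_sq_dist_sum_lattice(
        np.ascontiguousarray(heavy_coords, dtype=float),
        grid.inside, grid.origin, grid.spacing, 0.5 * grid.spacing))


def cavity_penalty(pose: Ligand, grid, weight: float = 1.0) -> float:
    mol = pose.molecule
    return cavity_penalty_coords(mol.coords[mol.heavy_mask], grid, weight)


def nmr_distance_penalty(pose_coords, rec: Receptor, dr: DistanceRestraint) -> float:
    """Quadratic flat-bottom penalty on the minimum selected-pair distance.

    Default semantics are NOE-style upper bounds: zero while the closest
    ligand/receptor atom pair is within ``bound``, quadratic beyond;
    ``lower_bound=True`` penalises pairs closer than the bound instead.
    """
    if not dr.ligand_atoms or not dr.receptor_atoms:
        raise ValueError("distance restraint selectors must resolve to atoms")
    la = np.asarray(pose_coords)[list(dr.ligand_atoms)]
    ra = rec.molecule.coords[list(dr.receptor_atoms)]
    d = np.linalg.norm(la[:, None, :] - ra[None, :, :], axis=-1).min()
    if dr.lower_bound:
        return float(dr.weight * max(0.0, dr.bound - d) ** 2)
    return float(dr.weight * max(0.0, d - dr.bound) ** 2)


def restraint_score(lig: Ligand, lig_coords, rec: Receptor,
                    rs: RestraintSet, index_map: dict | None = None) -> float:
    """Pharmacophore + distance-restraint penalty for one pose."""
    total = 0.0
    if rs.pharmacophores:
        if index_map is None:
            index_map = feature_index_map(lig.molecule)
        feats = features_from_indices(lig_coords, index_map)
        total += pharmacophore_penalty(feats, rs)
    for dr in rs.distance_restraints:
        total += nmr_distance_penalty(lig_coords, rec, dr)
    return total


# ----------------------------------------------------------------------
# restraint definition file

_TYPE_ALIASES = {
    "HBA": "neutral HBA", "HBD": "neutral HBD", "HYD": "hydrophobic",
    "ALI": "hydrophobic aliphatic", "ARO": "hydrophobic aromatic",
    "NEG": "negative", "POS": "positive", "ANY": "any heavy atom",
}


def parse_restraint_file(path) -> RestraintSet:
    """Plain-text pharmacophore file: optional ``NOPT n`` header, then one
    restraint per line: ``x y z radius TYPE [MANDATORY|OPTIONAL]``."""
    n_opt = 0
    phs = []
    with open(path) as fh:
        for raw in fh:
            s = raw.split("#")[0].strip()
            if not s:
                continue
            parts = s.split()
            if parts[0].upper() == "NOPT":
                n_opt = int(parts[1])
                continue
            x, y, z, radius = map(float, parts[:4])
            ftype = _TYPE_ALIASES.get(parts[4].upper(), parts[4])
            mandatory = True
            if len(parts) > 5:
                mandatory = parts[5].upper() != "OPTIONAL"
            phs.append(PharmacophoreRestraint(ftype, (x, y, z), radius, mandatory))
    return RestraintSet(pharmacophores=phs, n_opt=n_opt)
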