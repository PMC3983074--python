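"""Synthetic toy systems with known ground truth.

Every other module is testable without external data: toy ligands are small
organic molecules built programmatically (RDKit ETKDG geometry), toy
receptors are idealised spherical-shell "cages" of real-element pseudo-atoms
(C shell, O / O-H polar sites) so interaction typing applies unchanged, and
redocking complexes are built by wrapping a cage around a ligand
conformation with polar sites placed complementary to the ligand's donors
and acceptors — the constructed placement, locally refined by Simplex, is
the stored optimum.

For flexible ligands the stored optimum is the best pose found by the
documented construct-and-refine protocol, recorded as such — not a claim of
global optimality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .model import Ligand, Molecule, Receptor
from .torsions import make_ligand

__all__ = ["ToyComplex", "make_toy_cage", "make_toy_ligand",
           "make_redocking_suite", "export_complex"]


# ----------------------------------------------------------------------
# graph builder for toy ligands

_VALENCE = {"C": 4, "N": 3, "O": 2, "H": 1}


class _GraphBuilder:
    def __init__(self):
        self.elements: list[str] = []
        self.bonds: list[tuple[int, int, float]] = []
        self.charges: list[int] = []

    def atom(self, el: str, charge: int = 0) -> int:
        self.elements.append(el)
        self.charges.append(charge)
        return len(self.elements) - 1

    def bond(self, i: int, j: int, order: float = 1.0):
        self.bonds.append((i, j, order))

    def fill_hydrogens(self):
        used = [0.0] * len(self.elements)
        for i, j, o in self.bonds:
            used[i] += o
            used[j] += o
        for i, el in enumerate(list(self.elements)):
            if el == "H":
                continue
            val = _VALENCE.get(el, 4) + self.charges[i]
            n_h = int(round(val - used[i]))
            if n_h < 0:
                raise ValueError(f"over-valent atom {el} in toy graph")
            for _ in range(n_h):
                h = self.atom("H")
                self.bond(i, h)

    def to_molecule(self, name: str) -> Molecule:
        coords = np.zeros((len(self.elements), 3))
        return Molecule(self.elements, coords, self.bonds,
                        formal_charges=self.charges, name=name)


_FEATURE_BUILDERS = {}


def _feat(name):
    def deco(fn):
        _FEATURE_BUILDERS[name] = fn
        return fn
    return deco


@_feat("neutral HBA")
def _add_hba(g: _GraphBuilder, anchor: int):
    o = g.atom("O")
    g.bond(anchor, o, 2.0)  # ketone / aldehyde oxygen


@_feat("neutral HBD")
def _add_hbd(g: _GraphBuilder, anchor: int):
    # a primary amine: donates two H-bonds but (unlike a hydroxyl) does not
    # also accept, which keeps toy binding modes free of swapped assignments
    n = g.atom("N")
    g.bond(anchor, n, 1.0)  # NH2 hydrogens added by fill_hydrogens


@_feat("negative")
def _add_neg(g: _GraphBuilder, anchor: int):
    c = g.atom("C")
    o1 = g.atom("O")
    o2 = g.atom("O", charge=-1)
    g.bond(anchor, c)
    g.bond(c, o1, 2.0)
    g.bond(c, o2, 1.0)


@_feat("positive")
def _add_pos(g: _GraphBuilder, anchor: int):
    n = g.atom("N", charge=1)
    g.bond(anchor, n)  # ammonium; 3 H added by fill_hydrogens


@_feat("hydrophobic aromatic")
def _add_aromatic(g: _GraphBuilder, anchor: int):
    ring = [g.atom("C") for _ in range(6)]
    for k in range(6):
        g.bond(ring[k], ring[(k + 1) % 6], 1.5)
    g.bond(anchor, ring[0])


@_feat("hydrophobic")
def _add_methyl(g: _GraphBuilder, anchor: int):
    c = g.atom("C")
    g.bond(anchor, c)


_FEATURE_BUILDERS["hydrophobic aliphatic"] = _FEATURE_BUILDERS["hydrophobic"]
_FEATURE_BUILDERS["any heavy atom"] = _FEATURE_BUILDERS["hydrophobic"]


def _chain_graph(k: int, features, placements) -> Molecule:
    g = _GraphBuilder()
    chain = [g.atom("C") for _ in range(k)]
    for a, b in zip(chain, chain[1:]):
        g.bond(a, b)
    for ft, pos in zip(features, placements):
        _FEATURE_BUILDERS[ft](g, chain[pos])
    g.fill_hydrogens()
    return g.to_molecule("toy")


def _embed(mol: Molecule, seed: int) -> Molecule:
    """3D coordinates via RDKit ETKDG (deterministic under the seed)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    from .io_sdf import molecule_to_molblock

    rd = Chem.MolFromMolBlock(molecule_to_molblock(mol), sanitize=True,
                              removeHs=False)
    if rd is None:
        raise ValueError("toy ligand graph failed sanitisation")
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    if AllChem.EmbedMolecule(rd, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rd, params) != 0:
            raise ValueError("embedding failed for toy ligand")
    conf = rd.GetConformer()
    out = mol.copy()
    out.coords = np.array([list(conf.GetAtomPosition(i))
                           for i in range(rd.GetNumAtoms())])
    return out


def make_toy_ligand(seed: int, n_heavy: int = 6, n_rotatable: int = 1,
                    features=("neutral HBA",)) -> Ligand:
    """Chemically plausible chain molecule with an exact rotor count and the
    requested feature inventory.

    The backbone length and feature placements are searched until the
    perceived rotatable-bond count matches ``n_rotatable`` exactly; raises
    ``ValueError`` for infeasible combinations.  ``n_heavy`` guides the
    minimum backbone size.
    """
    if n_heavy < 1:
        raise ValueError("need at least one heavy atom")
    features = list(features)
    for ft in features:
        if ft not in _FEATURE_BUILDERS:
            raise ValueError(f"unknown feature type {ft!r}")
    k_min = max(1, n_heavy - 3 * len(features))
    for k in range(k_min, k_min + 30):
        for spread in (True, False):
            nf = len(features)
            if nf == 0:
                placements = []
            elif spread and nf > 1 and k > 1:
                placements = [round(i * (k - 1) / (nf - 1)) for i in range(nf)]
            else:
                placements = [min(i, k - 1) for i in range(nf)]
            try:
                mol = _chain_graph(k, features, placements)
                lig = make_ligand(mol)
            except ValueError:
                continue
            if len(lig.rotatable_dihedrals) == n_rotatable:
                try:
                    emb = _embed(mol, seed + 7919 * k)
                except ValueError:
                    continue
                lig = make_ligand(emb)
                if len(lig.rotatable_dihedrals) == n_rotatable:
                    if features:
                        from .restraints import detect_features

                        found = detect_features(lig)
                        if any(len(found[ft]) == 0 for ft in features):
                            continue
                    return lig
    raise ValueError(f"no toy ligand with {n_rotatable} rotors and "
                     f"features {features!r} found")


# ----------------------------------------------------------------------
# toy receptors


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def make_toy_cage(seed: int, pocket_radius: float = 6.0,
                  n_shell_atoms: int = 80, polar_sites: int = 0,
                  opening_cos: float = 0.85, jitter: float = 0.25) -> Receptor:
    """Spherical shell of apolar carbon pseudo-atoms with an opening at the
    +z pole, plus optional donor/acceptor oxygens on the pocket wall.

    Deterministic under the seed (positions carry a small seeded jitter to
    break the shell's symmetry).
    """
    if n_shell_atoms < 20:
        raise ValueError("need at least 20 shell atoms")
    rng = np.random.default_rng(seed)
    pts = _fibonacci_sphere(n_shell_atoms) * pocket_radius
    pts = pts + rng.normal(scale=jitter, size=pts.shape)
    keep = pts[:, 2] < opening_cos * pocket_radius  # opening at the +z pole
    pts = pts[keep]

    g = _GraphBuilder()
    for p in pts:
        g.atom("C")
    coords = list(pts)
    n_polar = min(polar_sites, len(pts))
    # convert evenly spaced wall atoms into polar sites: alternate bare
    # acceptor oxygens and O-H donors with the hydrogen pointing inward
    polar_idx = np.linspace(0, len(pts) - 1, n_polar).astype(int) if n_polar else []
    for m, i in enumerate(polar_idx):
        g.elements[i] = "O"
        if m % 2 == 1:
            h = g.atom("H")
            g.bond(i, h)
            inward = -pts[i] / np.linalg.norm(pts[i])
            coords.append(pts[i] + inward * 0.97)
    mol = Molecule(g.elements, np.array(coords), g.bonds,
                   formal_charges=g.charges, name=f"toy-cage-{seed}")
    from .atomtypes import assign_interaction_classes

    assign_interaction_classes(mol)
    return Receptor(mol)


# ----------------------------------------------------------------------
# redocking complexes


@dataclass
class ToyComplex:
    receptor: Receptor
    ligand: Ligand            # input conformation, placed at the optimum
    optimal_pose: np.ndarray  # coordinates of the refined optimum
    optimal_score: float
    cavity: object            # CavityGrid mapped from the reference ligand
    metadata: dict = field(default_factory=dict)


def _build_cage_around(lig: Ligand, rng, wall_gap: float = 3.8,
                       directions_per_atom: int = 42) -> Receptor:
    """Wrap a moulded carbon shell + complementary polar sites around a
    ligand conformation.

    Shell atoms sit on the outward surface of the union of spheres of radius
    ``wall_gap`` (slightly beyond the carbon-carbon pair optimum, keeping
    the pocket enterable for bulky ligands) around the ligand heavy
    atoms, so the wrapped conformation is simultaneously the polar and the
    vdW optimum — a constructed, funnel-shaped landscape.
    """
    mol = lig.molecule
    heavy = mol.coords[mol.heavy_mask]
    center = heavy.mean(axis=0)
    dirs = _fibonacci_sphere(directions_per_atom)
    cand = []
    for x in heavy:
        pts_x = x + dirs * wall_gap
        pts_x = pts_x + rng.normal(scale=0.12, size=pts_x.shape)
        cand.extend(pts_x)
    cand = np.array(cand)
    rng.shuffle(cand)
    pts = []
    for p in cand:
        d = np.linalg.norm(heavy - p, axis=1).min()
        if d < wall_gap - 0.4:       # inside the mould surface
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < 1.9:
            continue                  # carbon-carbon wall packing distance
        u = p - center
        if u[2] > 0.75 * np.linalg.norm(u):
            continue                  # pocket opening toward +z
        pts.append(p)
    pts = np.array(pts)

    g = _GraphBuilder()
    coords: list[np.ndarray] = []

    # complementary polar sites for every ligand donor-H and acceptor
    if mol.interaction_classes is None:
        from .atomtypes import assign_interaction_classes

        assign_interaction_classes(mol)
    polar_pts = []
    for i in range(mol.n_atoms):
        cls = mol.interaction_classes[i]
        if cls == "donor-H":
            root = mol.neighbors(i)[0]
            u = mol.coords[i] - mol.coords[root]
            u = u / np.linalg.norm(u)
            acc = mol.coords[root] + u * 2.8  # ideal D...A distance
            o = g.atom("O")
            coords.append(acc)
            polar_pts.append(acc)
        elif cls == "acceptor":
            roots = [k for k in mol.neighbors(i) if mol.elements[k] != "H"]
            if not roots:
                continue
            u = mol.coords[i] - mol.coords[roots[0]]
            u = u / np.linalg.norm(u)
            dpos = mol.coords[i] + u * 2.8
            # neutral N-H donor: donates but cannot accept, so H-bond
            # assignments cannot swap between wall sites
            nn = g.atom("N")
            coords.append(dpos)
            h = g.atom("H")
            g.bond(nn, h)
            coords.append(dpos - u * 1.02)  # H points back at the acceptor
            polar_pts.append(dpos)

    # shell atoms, dropping any that clash with the polar sites
    for p in pts:
        if polar_pts and np.min(np.linalg.norm(np.array(polar_pts) - p,
                                               axis=1)) < 2.4:
            continue
        g.atom("C")
        coords.append(p)

    rmol = Molecule(g.elements, np.array(coords), g.bonds,
                    formal_charges=g.charges, name="toy-pocket")
    from .atomtypes import assign_interaction_classes

    assign_interaction_classes(rmol)
    return Receptor(rmol)


def make_redocking_suite(n_systems: int = 20, seed: int = 0,
                         rotor_counts=None, ref_runs: int = 10) -> list[ToyComplex]:
    """Complexes with a constructed, Simplex-refined optimum.

    Rotor counts span 0-8 across the suite; ligands carry donor/acceptor
    anchors so the optimum is held by specific polar contacts.
    """
    from .cavity import map_reference_ligand
    from .params import ScoringConfig
    from .scoring import PoseScorer, score_pose
    from .search import ChromosomeCodec, simplex_minimize, _ChromScorer

    if n_systems < 1:
        raise ValueError("need at least one system")
    if rotor_counts is None:
        base = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 5, 5, 6, 6, 7, 7, 8, 2]
        rotor_counts = [base[i % len(base)] for i in range(n_systems)]
    # one acceptor + one donor anchor per ligand: chemically equivalent
    # duplicate anchors would create swap-degenerate optima
    feature_cycle = [
        ("neutral HBA", "neutral HBD"),
        ("neutral HBD", "neutral HBA"),
        ("neutral HBA", "neutral HBD", "hydrophobic aromatic"),
    ]
    out = []
    for i in range(n_systems):
        rng = np.random.default_rng(seed * 100003 + i)
        rot = rotor_counts[i]
        feats = feature_cycle[i % len(feature_cycle)]
        if rot == 0:
            # formamide-like: the amide C-N bond is not rotatable, so a
            # rigid ligand can still carry both anchor types
            feats = ("neutral HBA", "neutral HBD")
        elif rot == 1:
            # a single amine anchors through its two N-H donors
            feats = ("neutral HBD",)
        lig = make_toy_ligand(seed * 7919 + i, n_heavy=rot + 4,
                              n_rotatable=rot, features=feats)
        rec = _build_cage_around(lig, rng)
        cav = map_reference_ligand(rec, lig, radius=3.5, spacing=0.5,
                                   probe_allowance=0.0)
        cfg = ScoringConfig()
        scorer = PoseScorer(lig, rec, cav, None, cfg)
        codec = ChromosomeCodec(lig, rec)
        cs = _ChromScorer(codec, scorer)
        chrom = codec.encode(lig.molecule.coords)
        chrom, best = simplex_minimize(chrom, cs, max_evals=4000)
        opt_coords, _ = codec.decode(chrom)
        score = scorer.score(opt_coords).total
        # the stored optimum is the best pose found by a reference search
        # (construction + multi-run docking), recorded as best-found
        if ref_runs > 0:
            from .search import dock as _dock

            ref = _dock(lig, rec, cav, None, cfg, n_runs=ref_runs,
                        seed=[seed, i, 777])
            if ref[0].breakdown.total < score:
                opt_coords = ref[0].pose.molecule.coords
        # the stored ligand's input conformation IS the optimum (the usual
        # redocking setup); re-reference the score so S_intra = 0 there
        lig_opt = lig.with_coords(opt_coords)
        score = score_pose(lig_opt, rec, cav).total
        out.append(ToyComplex(
            receptor=rec,
            ligand=lig_opt,
            optimal_pose=opt_coords,
            optimal_score=float(score),
            cavity=cav,
            metadata={"seed": seed, "index": i, "rotors": rot,
                      "features": list(feats)},
        ))
    return out


def export_complex(cx: ToyComplex, directory, stem: str = "system") -> dict:
    """Write MOL2 (receptor), SDF (ligand at the optimum) and a JSON of
    expected values; returns the paths."""
    import os

    from .io_mol2 import write_mol2
    from .io_sdf import write_sdf

    os.makedirs(directory, exist_ok=True)
    rec_path = os.path.join(directory, f"{stem}_receptor.mol2")
    lig_path = os.path.join(directory, f"{stem}_ligand.sdf")
    json_path = os.path.join(directory, f"{stem}_expected.json")
    write_mol2(cx.receptor.molecule, rec_path)
    write_sdf([(cx.ligand.with_coords(cx.optimal_pose), None)], lig_path)
    with open(json_path, "w") as fh:
        json.dump({"optimal_score": cx.optimal_score,
                   "metadata": cx.metadata}, fh, indent=2)
    return {"receptor": rec_path, "ligand": lig_path, "expected": json_path}
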