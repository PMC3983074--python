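"""Molecular data model shared by every other module.

Coordinates are in Angstrom, right-handed Cartesian frame.  Atom indices are
0-based internally and converted to 1-based only at the MOL2/SDF boundary.

A :class:`Molecule` stores atoms as parallel arrays (fast for scoring) and
exposes an :class:`Atom` record view for inspection.  :class:`Receptor` and
:class:`Ligand` wrap a molecule together with its perceived flexible /
rotatable dihedrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "Receptor",
    "Ligand",
    "Dihedral",
    "measure_dihedral",
    "apply_dihedral",
    "set_dihedral",
    "principal_frame",
    "euler_to_matrix",
    "matrix_to_euler",
]

#: interaction classes an atom can carry (exactly one per atom)
INTERACTION_CLASSES = (
    "donor-H",          # polar hydrogen on N/O/S
    "acceptor",         # lone-pair bearing N/O/S heavy atom
    "polar-H carrier",  # heavy atom bearing a polar hydrogen but not an acceptor
    "apolar",           # carbon, halogen, hydrogen on carbon
    "metal",
    "other",
)

METALS = {
    "Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba", "Zn", "Mn", "Fe",
    "Co", "Ni", "Cu", "Cd", "Hg", "Al",
}
HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class Atom:
    """Read-only record view of one atom of a :class:`Molecule`."""

    index: int
    element: str
    position: np.ndarray
    formal_charge: int
    partial_charge: float
    interaction_class: str
    is_heavy: bool
    is_positive: bool = False
    is_negative: bool = False


class Molecule:
    """Atoms + bonds + rings + SD data fields, with order preserved from input.

    Parameters
    ----------
    elements : list of element symbols, one per atom.
    coords : (n, 3) float array, Angstrom.
    bonds : list of ``(i, j, order)`` with 0-based endpoints; order is 1, 2, 3
        or 1.5 for aromatic (MOL2 ``ar`` / SDF aromatic perception).
    formal_charges, partial_charges : per-atom arrays (defaults 0).
    rings : list of frozensets of atom indices (SSSR); perceived lazily from
        the bond graph when not supplied.
    sd_fields : ordered mapping of SD data-field name -> verbatim text block.
    """

    def __init__(self, elements, coords, bonds, formal_charges=None,
                 partial_charges=None, rings=None, name="", sd_fields=None):
        self.elements = list(elements)
        self.coords = np.asarray(coords, dtype=float).reshape(len(self.elements), 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        self.bonds = [(int(i), int(j), float(o)) for i, j, o in bonds]
        n = len(self.elements)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond endpoint out of range: ({i}, {j})")
        fc = np.zeros(n, dtype=int) if formal_charges is None else np.asarray(formal_charges, dtype=int)
        if np.any(np.abs(fc) > 4):
            raise ValueError("formal charge outside [-4, 4]")
        self.formal_charges = fc
        self.partial_charges = (np.zeros(n) if partial_charges is None
                                else np.asarray(partial_charges, dtype=float))
        self._rings = None if rings is None else [frozenset(r) for r in rings]
        self.name = name
        self.sd_fields = dict(sd_fields or {})
        # filled by atomtypes.assign_interaction_classes
        self.interaction_classes: list[str] | None = None
        self.positive_flags = np.zeros(n, dtype=bool)
        self.negative_flags = np.zeros(n, dtype=bool)

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.nonzero(self.heavy_mask)[0]

    @property
    def rings(self):
        if self._rings is None:
            self._rings = perceive_rings(self)
        return self._rings

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def bond_order(self, i: int, j: int) -> float | None:
        for a, b, o in self.bonds:
            if (a, b) == (i, j) or (a, b) == (j, i):
                return o
        return None

    def atom(self, i: int) -> Atom:
        cls = self.interaction_classes[i] if self.interaction_classes else "other"
        return Atom(
            index=i,
            element=self.elements[i],
            position=self.coords[i].copy(),
            formal_charge=int(self.formal_charges[i]),
            partial_charge=float(self.partial_charges[i]),
            interaction_class=cls,
            is_heavy=self.elements[i] != "H",
            is_positive=bool(self.positive_flags[i]),
            is_negative=bool(self.negative_flags[i]),
        )

    @property
    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def copy(self) -> "Molecule":
        m = Molecule(self.elements, self.coords.copy(), list(self.bonds),
                     self.formal_charges.copy(), self.partial_charges.copy(),
                     self._rings, self.name, dict(self.sd_fields))
        m.interaction_classes = (None if self.interaction_classes is None
                                 else list(self.interaction_classes))
        m.positive_flags = self.positive_flags.copy()
        m.negative_flags = self.negative_flags.copy()
        return m

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Molecule {self.name!r} atoms={self.n_atoms} bonds={len(self.bonds)}>"


def perceive_rings(mol: Molecule) -> list[frozenset]:
    """SSSR-style ring perception via the cycle basis of the bond graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    return [frozenset(c) for c in nx.minimum_cycle_basis(g)]


@dataclass
class Dihedral:
    """A rotatable torsion a-b-c-d.

    ``rotated_set`` is the connected component containing ``c`` and ``d``
    after deleting the b-c bond; rotating the dihedral moves exactly these
    atoms, about the b->c axis.
    """

    atom_indices: tuple[int, int, int, int]
    rotated_set: frozenset[int]

    def __post_init__(self):
        a, b, c, d = self.atom_indices
        if a in self.rotated_set or b in self.rotated_set:
            raise ValueError("a, b must not be in rotated_set")
        if c not in self.rotated_set or d not in self.rotated_set:
            raise ValueError("c, d must be in rotated_set")
        object.__setattr__(self, "_sorted_set", sorted(self.rotated_set))

    def flipped(self, mol: Molecule) -> "Dihedral":
        """Same bond, opposite rotated side (d-c-b-a orientation)."""
        a, b, c, d = self.atom_indices
        comp = _component_after_cut(mol, b, c)
        return Dihedral((d, c, b, a), frozenset(comp))

    def measure(self, coords: np.ndarray) -> float:
        return measure_dihedral(coords, *self.atom_indices)


def _component_after_cut(mol: Molecule, start: int, excluded_neighbor: int) -> set[int]:
    """Atoms reachable from ``start`` without crossing the start-excluded bond."""
    seen = {start}
    stack = [start]
    adj: dict[int, list[int]] = {}
    for i, j, _ in mol.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if u == start and v == excluded_neighbor:
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


# ----------------------------------------------------------------------
# torsion geometry


def _cross3(a, b):
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def measure_dihedral(coords: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    b1 = coords[b] - coords[a]
    b2 = coords[c] - coords[b]
    b3 = coords[d] - coords[c]
    n1 = _cross3(b1, b2)
    n2 = _cross3(b2, b3)
    m1 = _cross3(n1, b2 / math.sqrt(float(b2 @ b2)))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    ct, st = math.cos(t), math.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return ct * np.eye(3) + st * K + (1 - ct) * np.outer(axis, axis)


def apply_dihedral(coords: np.ndarray, dih: Dihedral, delta_deg: float) -> np.ndarray:
    """Rotate ``dih.rotated_set`` so the measured angle increases by
    ``delta_deg``.

    Returns new coordinates; atoms outside the rotated set are untouched.
    Because rotated sets of distinct acyclic bonds are nested or disjoint and
    axis endpoints are rotation-invariant, applying one dihedral never changes
    the measured angle of any other rotatable dihedral.
    """
    _, b, c, _ = dih.atom_indices
    axis = coords[c] - coords[b]
    # the measured angle increases when the distal side rotates by -delta
    # about the b->c direction (right-hand rule)
    R = _rotation_about_axis(axis, -delta_deg)
    out = coords.copy()
    idx = dih._sorted_set if dih._sorted_set is not None else sorted(dih.rotated_set)
    out[idx] = (coords[idx] - coords[b]) @ R.T + coords[b]
    return out


def set_dihedral(coords: np.ndarray, dih: Dihedral, target_deg: float) -> np.ndarray:
    """Rotate so that the measured a-b-c-d angle equals ``target_deg``."""
    return apply_dihedral(coords, dih, target_deg - dih.measure(coords))


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


# ----------------------------------------------------------------------
# rigid-body frames


def principal_frame(coords: np.ndarray) -> np.ndarray:
    """Sign-fixed principal-axes frame of a centred point set.

    Columns are the unit principal axes of the (unit-mass) gyration tensor,
    largest moment first.  Signs are fixed deterministically: axis k (k = 0, 1)
    is flipped so the first atom with a non-negligible projection projects
    positively; the third axis completes a right-handed frame.  For degenerate
    sets (single atom, perfectly symmetric) the frame falls back to identity
    columns for the undetermined directions.
    """
    pts = np.asarray(coords, dtype=float)
    com = pts.mean(axis=0)
    x = pts - com
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)  # ascending
    order = np.argsort(w)[::-1]
    axes = v[:, order]
    for k in range(2):
        proj = x @ axes[:, k]
        sign = 0.0
        for p in proj:
            if abs(p) > 1e-8:
                sign = math.copysign(1.0, p)
                break
        if sign < 0:
            axes[:, k] = -axes[:, k]
    axes[:, 2] = _cross3(axes[:, 0], axes[:, 1])
    return axes


def euler_to_matrix(heading: float, attitude: float, bank: float) -> np.ndarray:
    """Tait-Bryan z-y'-x'' (intrinsic) rotation matrix, angles in degrees."""
    ch, sh = math.cos(math.radians(heading)), math.sin(math.radians(heading))
    ca, sa = math.cos(math.radians(attitude)), math.sin(math.radians(attitude))
    cb, sb = math.cos(math.radians(bank)), math.sin(math.radians(bank))
    # Rz(h) @ Ry(a) @ Rx(b)
    return np.array([
        [ch * ca, ch * sa * sb - sh * cb, ch * sa * cb + sh * sb],
        [sh * ca, sh * sa * sb + ch * cb, sh * sa * cb - ch * sb],
        [-sa, ca * sb, ca * cb],
    ])


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    from scipy.spatial.transform import Rotation

    h, a, b = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
    return float(h), float(a), float(b)


# ----------------------------------------------------------------------
# receptor / ligand wrappers


@dataclass
class Receptor:
    molecule: Molecule
    flexible_dihedrals: list[Dihedral] = field(default_factory=list)


@dataclass
class Ligand:
    molecule: Molecule
    rotatable_dihedrals: list[Dihedral] = field(default_factory=list)

    def with_coords(self, coords: np.ndarray) -> "Ligand":
        m = self.molecule.copy()
        m.coords = np.asarray(coords, dtype=float).reshape(m.n_atoms, 3)
        return Ligand(m, self.rotatable_dihedrals)
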