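"""The composite empirical scoring function.

S_total is a weighted sum of four components:

* ``inter``  — ligand-receptor vdW + polar (+ desolvation for SF5);
* ``intra``  — ligand internal vdW/polar/torsion RELATIVE to the input
  conformation (exactly 0 at the input conformation by definition);
* ``site``   — flexible-receptor internal terms relative to the input;
* ``restraint`` — cavity containment + pharmacophore + tether/NMR biases.

The vdW term uses an n-m pair potential (4-8 early in the GA schedule, 6-12
for final scoring), Lorentz-Berthelot-style mixing and a short-range cap.
The polar term is a product of trapezoidal distance/angle ramps; same-class
pairs (donor-donor, acceptor-acceptor) are repulsive under SF3.  The
desolvation term weights per-atom changes in a probabilistic pairwise SASA.

:class:`PoseScorer` precomputes all pair bookkeeping for one ligand-receptor
system so a pose evaluation inside the search loop is a handful of
vectorised numpy operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Ligand, Molecule, Receptor
from .params import ScoringConfig, load_param_table, vdw_radius

__all__ = [
    "ScoreBreakdown",
    "vdw_pair_energy",
    "polar_pair_energy",
    "hasel_sasa",
    "desolvation_score",
    "ligand_dihedral_energy",
    "score_pose",
    "PoseScorer",
    "VdwGridSet",
    "build_vdw_grids",
]


@dataclass
class ScoreBreakdown:
    total: float
    inter: float
    intra: float
    site: float
    restraint: float
    sub_terms: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# closed-form pair terms


def vdw_pair_energy(r, r0, eps, form: str = "6-12", cap: float = math.inf):
    """n-m van der Waals pair energy, minimum -eps at r = r0.

    ``form`` is ``"6-12"`` (m=6, n=12) or ``"4-8"`` (m=4, n=8); in both
    cases n = 2m so E(r0) = -eps and the zero crossing sits at
    r0 * 2^(-1/m).  Energies are capped at ``cap`` for small r.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    m = {"6-12": 6, "4-8": 4}[form]
    x = (r0 / r) ** m
    return np.minimum(eps * (x * x - 2.0 * x), cap)


def _ramp_above(x, lo, tol):
    """1 for x >= lo, falling linearly to 0 at lo - tol."""
    return np.clip((x - (lo - tol)) / tol, 0.0, 1.0)


def _ramp_window(x, lo, hi, tol):
    """Trapezoid: 1 inside [lo, hi], linear to 0 across a band of width tol."""
    return np.minimum(np.clip((x - (lo - tol)) / tol, 0.0, 1.0),
                      np.clip(((hi + tol) - x) / tol, 0.0, 1.0))


def _ramp_above_s(x: float, lo: float, tol: float) -> float:
    return min(1.0, max(0.0, (x - (lo - tol)) / tol))


def _ramp_window_s(x: float, lo: float, hi: float, tol: float) -> float:
    up = min(1.0, max(0.0, (x - (lo - tol)) / tol))
    dn = min(1.0, max(0.0, ((hi + tol) - x) / tol))
    return min(up, dn)


def polar_pair_energy(donor_heavy, donor_h, acceptor, acceptor_root,
                      cfg: ScoringConfig, donor_charged: bool = False,
                      acceptor_charged: bool = False,
                      same_class: bool = False) -> float:
    """Empirical polar interaction for one donor/acceptor geometry.

    E = sign * W * f_dist(|D-A|) * f_ang(theta_DHA) * f_ang(phi_HAR); each f
    is a trapezoidal ramp (1 inside the ideal window, linear to 0 across the
    tolerance band, widths scaled by the stage relaxation factor).  Sign is
    negative (favourable) for donor-acceptor; for ``same_class`` pairs
    (donor-donor / acceptor-acceptor) a positive distance-only clash term is
    returned under SF3 and 0 in attractive-only mode.  Each charged partner
    multiplies the magnitude by the configured factor.
    """
    p = load_param_table()["polar"]
    dtol = cfg.polar_distance_tolerance * cfg.polar_tolerance_scale
    atol = cfg.polar_angle_tolerance * cfg.polar_tolerance_scale
    lo, hi = p["distance_window"]
    mult = p["charged_multiplier"] ** (int(donor_charged) + int(acceptor_charged))

    if same_class:
        if cfg.polar_mode != "attractive+repulsive":
            return 0.0
        d = float(np.linalg.norm(np.asarray(donor_heavy) - np.asarray(acceptor)))
        return float(p["repulsive_weight"] * mult
                     * _ramp_window(d, lo, hi, dtol))

    D = np.asarray(donor_heavy, dtype=float)
    H = np.asarray(donor_h, dtype=float)
    A = np.asarray(acceptor, dtype=float)
    R = np.asarray(acceptor_root, dtype=float) if acceptor_root is not None else None
    d = float(np.linalg.norm(D - A))
    f = _ramp_window(d, lo, hi, dtol)
    th = _angle(D - H, A - H)
    f *= _ramp_above(th, p["donor_angle_window"][0], atol)
    if R is not None:
        ph = _angle(H - A, R - A)
        f *= _ramp_above(ph, p["acceptor_angle_window"][0], atol)
    return float(-p["well_depth"] * mult * f)


def _angle(v1, v2):
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def _angles(V1, V2):
    """Pairwise angles (degrees) between broadcastable (..., 3) arrays."""
    num = (V1 * V2).sum(-1)
    den = np.sqrt((V1 * V1).sum(-1) * (V2 * V2).sum(-1)) + 1e-12
    return np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))


# ----------------------------------------------------------------------
# probabilistic SASA + desolvation


def hasel_sasa(elements, coords, bonded_pairs=(), solvent_radius=None):
    """Per-atom approximate SASA via the pairwise-overlap product formula.

    A_i = S_i * prod_j (1 - p_i * p_ij * b_ij(r_ij) / S_i) with
    S_i = 4 pi (r_i + r_solv)^2 and b_ij the pairwise sphere-overlap area;
    p parameters come from the shipped table (1-2 neighbours get the bonded
    parameter).  Results are clamped to [0, S_i].
    """
    p = load_param_table()["sasa"]
    rs = p["solvent_radius"] if solvent_radius is None else solvent_radius
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    R = np.array([vdw_radius(e) + rs for e in elements])
    S = 4.0 * math.pi * R ** 2
    p_atom = np.array([p["p_atom"].get(e, p["p_atom"]["default"]) for e in elements])
    bonded = {frozenset(b) for b in bonded_pairs}

    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(r, np.inf)
    r = np.maximum(r, p["distance_floor"])

    Ri = R[:, None]
    Rj = R[None, :]
    b = math.pi * Ri * (Ri + Rj - r) * (1.0 + (Rj - Ri) / r)
    b = np.clip(b, 0.0, S[:, None])
    b[r >= Ri + Rj] = 0.0

    pij = np.full((n, n), p["p_nonbonded"])
    for pair in bonded:
        i, j = tuple(pair)
        pij[i, j] = pij[j, i] = p["p_bonded"]
    factors = np.clip(1.0 - p_atom[:, None] * pij * b / S[:, None], 0.0, 1.0)
    return S * np.prod(factors, axis=1)


def _mol_bonded_pairs(mol: Molecule, offset: int = 0):
    return [(i + offset, j + offset) for i, j, _ in mol.bonds]


def desolvation_score(lig_coords, lig: Ligand, rec: Receptor,
                      cfg: ScoringConfig | None = None,
                      rec_free_sasa=None, lig_classes=None) -> float:
    """Sum over ligand and site atoms of w_class * (SASA_bound - SASA_free)."""
    lm, rm = lig.molecule, rec.molecule
    if lm.interaction_classes is None:
        from .atomtypes import assign_interaction_classes

        assign_interaction_classes(lm)
    if rm.interaction_classes is None:
        from .atomtypes import assign_interaction_classes

        assign_interaction_classes(rm)
    w = load_param_table()["desolvation_weights"]
    elements = lm.elements + rm.elements
    coords = np.vstack([lig_coords, rm.coords])
    bonded = _mol_bonded_pairs(lm) + _mol_bonded_pairs(rm, offset=lm.n_atoms)
    a_bound = hasel_sasa(elements, coords, bonded)
    a_free_lig = hasel_sasa(lm.elements, lig_coords, _mol_bonded_pairs(lm))
    if rec_free_sasa is None:
        rec_free_sasa = hasel_sasa(rm.elements, rm.coords, _mol_bonded_pairs(rm))
    a_free = np.concatenate([a_free_lig, rec_free_sasa])
    classes = lm.interaction_classes + rm.interaction_classes
    weights = np.array([w.get(c, 0.0) for c in classes])
    return float(np.sum(weights * (a_bound - a_free)))


# ----------------------------------------------------------------------
# ligand torsional potential


def _torsion_barrier(mol: Molecule, dih) -> float:
    t = load_param_table()["torsion_barriers"]
    _, b, c, _ = dih.atom_indices
    key = "-".join(sorted((mol.elements[b], mol.elements[c])))
    return float(t.get(key, t["default"]))


def ligand_dihedral_energy(lig: Ligand, cfg: ScoringConfig,
                           coords=None, angles=None) -> float:
    """3-fold cosine torsional potential over the rotatable dihedrals.

    E = sum_k (V_k / 2) (1 + cos 3 theta_k), scaled by the stage's dihedral
    weight; minima at the staggered angles (+-60, 180 degrees).  ``angles``
    (degrees, one per rotatable dihedral) skips re-measuring them from the
    coordinates.
    """
    if angles is None:
        coords = lig.molecule.coords if coords is None else coords
        angles = [dih.measure(coords) for dih in lig.rotatable_dihedrals]
    e = 0.0
    for dih, theta in zip(lig.rotatable_dihedrals, angles):
        v = _torsion_barrier(lig.molecule, dih)
        e += 0.5 * v * (1.0 + math.cos(3.0 * math.radians(theta)))
    return cfg.dihedral_weight_scale * e


# ----------------------------------------------------------------------
# vdW parameter mixing


def _well(element: str):
    t = load_param_table()["vdw_well"]
    from .model import METALS

    if element in METALS:
        w = t["metal"]
    else:
        w = t.get(element, t["default"])
    return float(w["r0"]), float(w["eps"])


def _mix(el_a, el_b):
    r0a, ea = _well(el_a)
    r0b, eb = _well(el_b)
    return 0.5 * (r0a + r0b), math.sqrt(ea * eb)


# ----------------------------------------------------------------------
# vdW grids


@dataclass
class VdwGridSet:
    """Precomputed receptor vdW field, one lattice per ligand element class.

    Lattice values at grid points equal the direct capped pair sum exactly;
    off-lattice lookups are trilinear.
    """

    origin: np.ndarray
    spacing: float
    form: str
    values: dict  # element -> (nx, ny, nz) array

    def interpolate(self, element: str, points: np.ndarray) -> np.ndarray:
        grid = self.values[element]
        pts = (np.atleast_2d(points) - self.origin) / self.spacing
        shape = np.array(grid.shape)
        if np.any(pts < 0) or np.any(pts > shape - 1):
            raise ValueError("pose outside vdW lattice bounds")
        i0 = np.minimum(pts.astype(int), shape - 2)
        f = pts - i0
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        c = 0.0
        for dx in (0, 1):
            wx = fx if dx else 1.0 - fx
            for dy in (0, 1):
                wy = fy if dy else 1.0 - fy
                for dz in (0, 1):
                    wz = fz if dz else 1.0 - fz
                    c = c + grid[ix + dx, iy + dy, iz + dz] * wx * wy * wz
        return c


def build_vdw_grids(rec: Receptor, cavity, spacing: float = 0.3,
                    cfg: ScoringConfig | None = None,
                    elements=("H", "C", "N", "O", "S", "F", "Cl"),
                    margin: float = 4.0) -> VdwGridSet:
    """Precalculate the receptor vdW field over the cavity bounding box.

    Value at point p for ligand class e = sum over receptor atoms of the
    capped pair energy; the lattice covers the cavity bounding box plus
    ``margin`` on every side.
    """
    cfg = cfg or ScoringConfig()
    pts_in = cavity.cavity_points
    lo = pts_in.min(axis=0) - margin
    hi = pts_in.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid_pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    rm = rec.molecule
    values = {}
    for el in elements:
        total = np.zeros(len(grid_pts))
        for j in range(rm.n_atoms):
            r0, eps = _mix(el, rm.elements[j])
            d = np.linalg.norm(grid_pts - rm.coords[j], axis=1)
            d = np.maximum(d, 1e-6)
            total += vdw_pair_energy(d, r0, eps, cfg.vdw_form, cfg.vdw_cap)
        values[el] = total.reshape(tuple(shape))
    return VdwGridSet(lo, spacing, cfg.vdw_form, values)


# ----------------------------------------------------------------------
# the pose scorer


class PoseScorer:
    """Precomputed scorer for one ligand/receptor/cavity/restraint system.

    ``score(lig_coords, rec_coords=None)`` returns a :class:`ScoreBreakdown`
    and is a pure function of its inputs.  ``cfg`` may be swapped between
    search stages via :meth:`set_config`.
    """

    def __init__(self, lig: Ligand, rec: Receptor, cavity=None,
                 restraints=None, cfg: ScoringConfig | None = None,
                 grids: VdwGridSet | None = None):
        from .atomtypes import assign_interaction_classes

        self.lig, self.rec = lig, rec
        self.cavity = cavity
        self.restraints = restraints
        self.cfg = (cfg or ScoringConfig()).validate()
        self.grids = grids
        lm, rm = lig.molecule, rec.molecule
        if lm.interaction_classes is None:
            assign_interaction_classes(lm)
        if rm.interaction_classes is None:
            assign_interaction_classes(rm)
        if self.cfg.use_desolvation:
            self._rec_free_sasa = hasel_sasa(rm.elements, rm.coords,
                                             _mol_bonded_pairs(rm))
        else:
            self._rec_free_sasa = None

        # --- inter vdW pair parameters (ligand x receptor, all atoms)
        nl, nr = lm.n_atoms, rm.n_atoms
        self._r0 = np.empty((nl, nr))
        self._eps = np.empty((nl, nr))
        for i in range(nl):
            for j in range(nr):
                self._r0[i, j], self._eps[i, j] = _mix(lm.elements[i], rm.elements[j])

        # --- polar bookkeeping
        self._lig_donors = _donor_list(lm)      # (H idx, heavy root idx)
        self._lig_acceptors = _acceptor_list(lm)  # (A idx, root idx or -1)
        self._rec_donors = _donor_list(rm)
        self._rec_acceptors = _acceptor_list(rm)
        self._lig_don_flags = [bool(lm.positive_flags[r]) for _, r in self._lig_donors]
        self._lig_acc_flags = [bool(lm.negative_flags[a]) for a, _ in self._lig_acceptors]
        self._rec_don_flags = [bool(rm.positive_flags[r]) for _, r in self._rec_donors]
        self._rec_acc_flags = [bool(rm.negative_flags[a]) for a, _ in self._rec_acceptors]
        p = load_param_table()["polar"]
        self._polar_params = p

        def arrs(pairs, flags):
            idx = np.array([x for x, _ in pairs], dtype=np.int64)
            root = np.array([r for _, r in pairs], dtype=np.int64)
            return (idx, root, np.array(flags, dtype=np.int64),
                    root >= 0, np.maximum(root, 0))

        self._ld = arrs(self._lig_donors, self._lig_don_flags)
        self._la = arrs(self._lig_acceptors, self._lig_acc_flags)
        self._rd = arrs(self._rec_donors, self._rec_don_flags)
        self._ra = arrs(self._rec_acceptors, self._rec_acc_flags)
        self._ones_lr = np.ones((len(self._lig_donors), len(self._rec_acceptors)))
        self._ones_rl = np.ones((len(self._rec_donors), len(self._lig_acceptors)))
        # intra donor/acceptor pair mask: more than 3 bonds apart
        if len(self._lig_donors) and len(self._lig_acceptors):
            self._intra_polar_mask = np.array(
                [[self._graph_dist(h, a) > 3 for a, _ in self._lig_acceptors]
                 for h, _ in self._lig_donors], dtype=float)
        else:
            self._intra_polar_mask = None
        self._heavy_idx = lm.heavy_indices

        # --- intra-ligand pair lists (1-2, 1-3 excluded; 1-4 scaled)
        self._intra_pairs, self._intra_scale = _intra_pairs(lm, self.cfg.scale_14)
        if len(self._intra_pairs):
            self._intra_r0 = np.array([_mix(lm.elements[i], lm.elements[j])[0]
                                       for i, j in self._intra_pairs])
            self._intra_eps = np.array([_mix(lm.elements[i], lm.elements[j])[1]
                                        for i, j in self._intra_pairs])
        self._barriers = np.array([_torsion_barrier(lm, d)
                                   for d in lig.rotatable_dihedrals])
        self._ref_coords = lm.coords.copy()
        self._rec_ref_coords = rm.coords.copy()
        self._intra_ref = None  # filled lazily per cfg (depends on schedule)
        self._site_ref = None
        self._intra_cache: dict = {}

    # -- configuration -------------------------------------------------
    def set_config(self, cfg: ScoringConfig):
        self.cfg = cfg.validate()
        self._intra_ref = None
        self._site_ref = None
        self._intra_cache: dict = {}
        return self

    # -- components ----------------------------------------------------
    def inter_vdw(self, lig_coords, rec_coords=None, use_grids=None):
        lm = self.lig.molecule
        use_grids = (self.grids is not None) if use_grids is None else use_grids
        if use_grids:
            if self.grids is None:
                raise ValueError("grid mode requested but no grids supplied")
            if self.grids.form != self.cfg.vdw_form:
                raise ValueError("grid form does not match scoring config")
            total = 0.0
            for el in set(lm.elements):
                idx = [i for i, e in enumerate(lm.elements) if e == el]
                total += float(np.sum(self.grids.interpolate(el, lig_coords[idx])))
            return total
        from ._kernels import vdw_sum

        rc = self._rec_ref_coords if rec_coords is None else rec_coords
        m = 6 if self.cfg.vdw_form == "6-12" else 4
        return float(vdw_sum(lig_coords, rc, self._r0, self._eps, m,
                             self.cfg.vdw_cap))

    def _attractive_block(self, don, don_xyz, acc, acc_xyz, mask=None) -> float:
        """Compiled donor->acceptor sum: E = -W*mult*f_d*f_theta*f_phi."""
        from ._kernels import polar_attract

        h_idx, d_idx, d_flag, _, _ = don
        a_idx, _, a_flag, has_root, r_safe = acc
        if len(h_idx) == 0 or len(a_idx) == 0:
            return 0.0
        p = self._polar_params
        cfg = self.cfg
        dtol = cfg.polar_distance_tolerance * cfg.polar_tolerance_scale
        atol = cfg.polar_angle_tolerance * cfg.polar_tolerance_scale
        lo, hi = p["distance_window"]
        if mask is None:
            mask = (self._ones_lr if don is self._ld and acc is self._ra
                    else self._ones_rl)
        return float(polar_attract(
            don_xyz[d_idx], don_xyz[h_idx], d_flag,
            acc_xyz[a_idx], acc_xyz[r_safe], has_root, a_flag, mask,
            lo, hi, dtol, p["donor_angle_window"][0],
            p["acceptor_angle_window"][0], atol,
            p["well_depth"], p["charged_multiplier"]))

    def inter_polar(self, lig_coords, rec_coords=None):
        from ._kernels import polar_total

        rc = self._rec_ref_coords if rec_coords is None else rec_coords
        p = self._polar_params
        cfg = self.cfg
        dtol = cfg.polar_distance_tolerance * cfg.polar_tolerance_scale
        atol = cfg.polar_angle_tolerance * cfg.polar_tolerance_scale
        lo, hi = p["distance_window"]
        return float(polar_total(
            lig_coords, rc,
            self._ld[0], self._ld[1], self._ld[2],
            self._la[0], self._la[4], self._la[3], self._la[2],
            self._rd[0], self._rd[1], self._rd[2],
            self._ra[0], self._ra[4], self._ra[3], self._ra[2],
            lo, hi, dtol, p["donor_angle_window"][0],
            p["acceptor_angle_window"][0], atol, p["well_depth"],
            p["charged_multiplier"], p["repulsive_weight"],
            cfg.polar_mode == "attractive+repulsive"))

    def _intra_raw(self, lig_coords, angles=None):
        """Ligand internal vdW + polar + dihedral at given coordinates."""
        lm = self.lig.molecule
        e = 0.0
        if len(self._intra_pairs):
            from ._kernels import pair_vdw_sum

            m = 6 if self.cfg.vdw_form == "6-12" else 4
            e += float(pair_vdw_sum(lig_coords, self._intra_pairs[:, 0],
                                    self._intra_pairs[:, 1], self._intra_r0,
                                    self._intra_eps, self._intra_scale, m,
                                    self.cfg.vdw_cap))
        # intra polar: donor/acceptor pairs more than 3 bonds apart
        if self._intra_polar_mask is not None:
            e += self._attractive_block(self._ld, lig_coords, self._la,
                                        lig_coords, self._intra_polar_mask)
        if angles is not None and len(self._barriers):
            th = np.radians(np.asarray(angles, dtype=float))
            e += self.cfg.dihedral_weight_scale * float(
                np.sum(0.5 * self._barriers * (1.0 + np.cos(3.0 * th))))
        else:
            e += ligand_dihedral_energy(self.lig, self.cfg, lig_coords, angles)
        return e

    def _graph_dist(self, i, j):
        if not hasattr(self, "_gdist"):
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(self.lig.molecule.n_atoms))
            g.add_edges_from((a, b) for a, b, _ in self.lig.molecule.bonds)
            self._gdist = dict(nx.all_pairs_shortest_path_length(g))
        return self._gdist[i].get(j, 99)

    def intra(self, lig_coords, lig_dihedral_angles=None):
        if not self.lig.rotatable_dihedrals:
            return 0.0
        if self._intra_ref is None:
            self._intra_ref = self._intra_raw(self._ref_coords)
        # the ligand-internal energy is rigid-motion invariant, hence a
        # function of the dihedral angles alone
        if lig_dihedral_angles is not None:
            key = np.asarray(lig_dihedral_angles).tobytes()
            cached = self._intra_cache.get(key)
            if cached is None:
                cached = float(self._intra_raw(lig_coords, lig_dihedral_angles)
                               - self._intra_ref)
                if len(self._intra_cache) > 20000:
                    self._intra_cache.clear()
                self._intra_cache[key] = cached
            return cached
        return float(self._intra_raw(lig_coords) - self._intra_ref)

    def site(self, rec_coords=None):
        if rec_coords is None or not self.rec.flexible_dihedrals:
            return 0.0
        if self._site_ref is None:
            self._site_ref = self._site_raw(self._rec_ref_coords)
        return float(self._site_raw(rec_coords) - self._site_ref)

    def _site_raw(self, rec_coords):
        rm = self.rec.molecule
        t = load_param_table()["torsion_barriers"]
        e = 0.0
        for dih in self.rec.flexible_dihedrals:
            key = "-".join(sorted((rm.elements[dih.atom_indices[1]],
                                   rm.elements[dih.atom_indices[2]])))
            v = float(t.get(key, t["default"]))
            e += 0.5 * v * (1.0 + math.cos(3.0 * math.radians(dih.measure(rec_coords))))
        return e

    def restraint_penalty(self, lig_coords):
        from . import restraints as rmod

        total, subs = 0.0, {}
        if self.cavity is not None:
            pen = rmod.cavity_penalty_coords(
                lig_coords[self.lig.molecule.heavy_mask], self.cavity)
            total += pen
            subs["restraint.cavity"] = pen
        if self.restraints is not None:
            if not hasattr(self, "_feature_map"):
                self._feature_map = rmod.feature_index_map(self.lig.molecule)
            pen = rmod.restraint_score(self.lig, lig_coords, self.rec,
                                       self.restraints, self._feature_map)
            total += pen
            subs["restraint.bias"] = pen
        return total, subs

    # -- the full breakdown ---------------------------------------------
    def score(self, lig_coords, rec_coords=None, use_grids=None,
              lig_dihedral_angles=None) -> ScoreBreakdown:
        cfg = self.cfg
        w = cfg.weights
        vdw = self.inter_vdw(lig_coords, rec_coords, use_grids)
        pol = self.inter_polar(lig_coords, rec_coords)
        subs = {"inter.vdw": vdw, "inter.polar": pol}
        inter = w["vdw"] * vdw + w["polar"] * pol
        if cfg.use_desolvation:
            des = desolvation_score(lig_coords, self.lig, self.rec, cfg,
                                    rec_free_sasa=self._rec_free_sasa)
            subs["inter.desolv"] = des
            inter += w["desolv"] * des
        intra = self.intra(lig_coords, lig_dihedral_angles)
        site = self.site(rec_coords)
        restraint, rsubs = self.restraint_penalty(lig_coords)
        subs.update(rsubs)
        total = (w["inter"] * inter + w["intra"] * intra
                 + w["site"] * site + w["restraint"] * restraint)
        return ScoreBreakdown(total, inter, intra, site, restraint, subs)


def _donor_list(mol: Molecule):
    out = []
    for i, cls in enumerate(mol.interaction_classes):
        if cls == "donor-H":
            nbrs = mol.neighbors(i)
            if nbrs:
                out.append((i, nbrs[0]))
    return out


def _acceptor_list(mol: Molecule):
    out = []
    for i, cls in enumerate(mol.interaction_classes):
        if cls == "acceptor":
            roots = [k for k in mol.neighbors(i) if mol.elements[k] != "H"]
            out.append((i, min(roots) if roots else -1))
    return out


def _intra_pairs(mol: Molecule, scale_14: float):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    pairs, scales = [], []
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            d = dist.get(i, {}).get(j)
            if d is not None and d <= 2:
                continue  # 1-2 / 1-3 excluded
            pairs.append((i, j))
            scales.append(scale_14 if d == 3 else 1.0)
    return np.array(pairs, dtype=int).reshape(-1, 2), np.array(scales)


def score_pose(lig: Ligand, rec: Receptor, cavity=None, restraints=None,
               cfg: ScoringConfig | None = None,
               grids: VdwGridSet | None = None) -> ScoreBreakdown:
    """Score one pose (the ligand's current coordinates) from scratch."""
    scorer = PoseScorer(lig, rec, cavity, restraints, cfg, grids)
    return scorer.score(lig.molecule.coords)
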