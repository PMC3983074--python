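"""Pose generation: chromosome encoding, staged GA search, MC refinement,
Simplex minimisation, multi-run docking and multi-step HTVS protocols.

A docking run is GA1 -> GA2 -> GA3 -> MC -> MIN.  The three GA stages share
a population but tighten the scoring function between stages: the
intermolecular vdW switches from the soft 4-8 form (GA1/GA2) to 6-12
(GA3/MC/MIN), polar distance/angle tolerances are progressively tightened,
and the ligand dihedral weight progressively raised; everything is at its
final value for MC/MIN.  A generation has passed when as many new
individuals have been created as the population size; the GA stops when the
best score improved by less than 0.1 units over the last three generations.

In tethered mode the chromosome's rigid-body genes are the substructure
translation (clamped to ``trans_tol``) and a rotation vector (clamped to
``rot_tol``) about the substructure centroid, and only dihedrals whose
rotation does not move tethered atoms are sampled — the tether is enforced
absolutely by construction, not by a penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .cavity import CavityGrid
from .model import (Ligand, Receptor, euler_to_matrix, matrix_to_euler,
                    principal_frame, set_dihedral)
from .params import ScoringConfig
from .scoring import PoseScorer, ScoreBreakdown

__all__ = [
    "Chromosome",
    "StageParams",
    "DockResult",
    "ChromosomeCodec",
    "default_schedule",
    "initialize_population",
    "mutate",
    "crossover",
    "run_ga_stage",
    "mc_refine",
    "simplex_minimize",
    "dock",
    "run_htvs",
]


def _wrap(a):
    a = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(a == -180.0, 180.0, a)


@dataclass
class Chromosome:
    """Search state: ligand COM, Euler orientation (heading, attitude, bank),
    ligand rotatable dihedrals and receptor rotatable dihedrals (degrees).

    In tethered mode ``com`` holds the substructure translation offset and
    ``euler`` a rotation vector; the codec documents the reinterpretation.
    """

    com: np.ndarray
    euler: np.ndarray
    ligand_dihedrals: np.ndarray
    receptor_dihedrals: np.ndarray

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.euler = np.asarray(self.euler, dtype=float).reshape(3)
        self.ligand_dihedrals = np.asarray(self.ligand_dihedrals, dtype=float).ravel()
        self.receptor_dihedrals = np.asarray(self.receptor_dihedrals, dtype=float).ravel()

    @property
    def n_dof(self) -> int:
        return 6 + len(self.ligand_dihedrals) + len(self.receptor_dihedrals)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.com, self.euler, self.ligand_dihedrals,
                               self.receptor_dihedrals])

    @classmethod
    def from_vector(cls, v, n_lig, n_rec) -> "Chromosome":
        v = np.asarray(v, dtype=float)
        return cls(v[:3], v[3:6], v[6:6 + n_lig], v[6 + n_lig:6 + n_lig + n_rec])

    def copy(self) -> "Chromosome":
        return Chromosome(self.com.copy(), self.euler.copy(),
                          self.ligand_dihedrals.copy(),
                          self.receptor_dihedrals.copy())


# ----------------------------------------------------------------------
# codec


class ChromosomeCodec:
    """Maps chromosomes to poses (and back) for one ligand/receptor system.

    Decoding applies the ligand dihedral angles to the input conformation,
    rotates the ligand principal axes from the Cartesian reference axes by
    the Tait-Bryan z-y'-x'' Euler angles, translates the centre of mass and
    applies the receptor dihedrals.  ``decode(encode(pose))`` reproduces
    coordinates to within numerical precision for non-degenerate shapes.
    """

    def __init__(self, lig: Ligand, rec: Receptor, tether=None):
        self.lig, self.rec = lig, rec
        self.ref_coords = lig.molecule.coords.copy()
        self.rec_ref = rec.molecule.coords.copy()
        self.tether = tether  # TetherContext or None
        if tether is not None:
            self.dihedrals = tether.free_dihedrals
            self.sub_idx = list(tether.mapping)
            self.sub_com = self.ref_coords[self.sub_idx].mean(axis=0)
        else:
            self.dihedrals = lig.rotatable_dihedrals
        self._ref_angles = np.array([d.measure(self.ref_coords)
                                     for d in self.dihedrals])
        if self.dihedrals:
            self._tor_b = np.array([d.atom_indices[1] for d in self.dihedrals],
                                   dtype=np.int64)
            self._tor_c = np.array([d.atom_indices[2] for d in self.dihedrals],
                                   dtype=np.int64)
            flat, off = [], [0]
            for d in self.dihedrals:
                flat.extend(d._sorted_set)
                off.append(len(flat))
            self._tor_idx = np.array(flat, dtype=np.int64)
            self._tor_off = np.array(off, dtype=np.int64)
        if not self.dihedrals and tether is None:
            # rigid ligand: the body frame never changes, precompute it
            com0 = self.ref_coords.mean(axis=0)
            self._rigid_body = (self.ref_coords - com0) @ principal_frame(self.ref_coords)
        else:
            self._rigid_body = None
        # body frames keyed by the dihedral gene bytes: most GA moves touch
        # the rigid-body genes only, so conformations repeat heavily
        self._body_cache: dict = {}

    @property
    def n_lig(self) -> int:
        return len(self.dihedrals)

    @property
    def n_rec(self) -> int:
        return len(self.rec.flexible_dihedrals)

    def _conformation(self, angles) -> np.ndarray:
        coords = self.ref_coords.copy()
        if self.dihedrals:
            from ._kernels import apply_torsions

            deltas = np.asarray(angles, dtype=float) - self._ref_angles
            apply_torsions(coords, self._tor_b, self._tor_c,
                           self._tor_idx, self._tor_off, deltas)
        return coords

    def decode(self, chrom: Chromosome):
        """Chromosome -> (ligand coords, receptor coords or None)."""
        if len(chrom.ligand_dihedrals) != self.n_lig \
                or len(chrom.receptor_dihedrals) != self.n_rec:
            raise ValueError("chromosome dihedral counts do not match system")
        if self.tether is not None:
            coords = self._conformation(chrom.ligand_dihedrals)
            t = _clamp_norm(chrom.com, self.tether.spec.trans_tol)
            rv = _clamp_norm(chrom.euler, self.tether.spec.rot_tol)
            R = Rotation.from_rotvec(np.radians(rv)).as_matrix()
            pose = (coords - self.sub_com) @ R.T + self.sub_com + t
        else:
            if self._rigid_body is not None:
                body = self._rigid_body
            else:
                key = chrom.ligand_dihedrals.tobytes()
                body = self._body_cache.get(key)
                if body is None:
                    coords = self._conformation(chrom.ligand_dihedrals)
                    com0 = coords.mean(axis=0)
                    body = (coords - com0) @ principal_frame(coords)
                    if len(self._body_cache) > 20000:
                        self._body_cache.clear()
                    self._body_cache[key] = body
            R = euler_to_matrix(*chrom.euler)
            pose = body @ R.T + chrom.com
        rec_coords = None
        if self.n_rec:
            rec_coords = self.rec_ref.copy()
            for dih, ang in zip(self.rec.flexible_dihedrals,
                                chrom.receptor_dihedrals):
                rec_coords = set_dihedral(rec_coords, dih, ang)
        return pose, rec_coords

    def encode(self, lig_coords, rec_coords=None) -> Chromosome:
        angles = [d.measure(lig_coords) for d in self.dihedrals]
        rec_angles = []
        if self.n_rec:
            rc = self.rec_ref if rec_coords is None else rec_coords
            rec_angles = [d.measure(rc) for d in self.rec.flexible_dihedrals]
        if self.tether is not None:
            sub = lig_coords[self.sub_idx]
            t = sub.mean(axis=0) - self.sub_com
            from .restraints import _kabsch

            R, _ = _kabsch(self.ref_coords[self.sub_idx] - self.sub_com,
                           lig_coords[self.sub_idx] - sub.mean(axis=0))
            rv = np.degrees(Rotation.from_matrix(R).as_rotvec())
            return Chromosome(t, rv, angles, rec_angles)
        com = lig_coords.mean(axis=0)
        euler = matrix_to_euler(principal_frame(lig_coords))
        return Chromosome(com, np.array(euler), angles, rec_angles)


def _clamp_norm(v, limit):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n > limit:
        return v * (limit / n) if n > 0 else v
    return v


@dataclass
class TetherContext:
    spec: object            # restraints.TetherSpec
    mapping: tuple          # ligand atom indices matched to the query
    free_dihedrals: list    # dihedrals whose rotation spares tethered atoms


def make_tether_context(lig: Ligand, spec, mapping) -> TetherContext:
    """Re-orient rotatable dihedrals away from the tethered substructure.

    Dihedrals whose rotated set would move matched atoms are flipped to
    rotate the opposite side; if both sides contain matched atoms the
    dihedral is frozen (dropped from the chromosome).
    """
    matched = set(mapping)
    free = []
    for dih in lig.rotatable_dihedrals:
        if dih.rotated_set & matched:
            flipped = dih.flipped(lig.molecule)
            if flipped.rotated_set & matched:
                continue
            free.append(flipped)
        else:
            free.append(dih)
    return TetherContext(spec, tuple(mapping), free)


# ----------------------------------------------------------------------
# stage schedule


@dataclass
class StageParams:
    stage: str                      # GA1 | GA2 | GA3 | MC | MIN
    vdw_form: str
    polar_tolerance_scale: float
    dihedral_weight_scale: float
    population_size: int = 50
    mutation_widths: dict = field(default_factory=lambda: {
        "com": 2.0, "euler": 30.0, "dihedral": 30.0})
    mc_temperature: float = 0.3
    mc_steps: int = 500
    max_generations: int = 100
    vdw_cap: float | None = None    # soft clash cap for early stages

    def apply(self, cfg: ScoringConfig) -> ScoringConfig:
        out = cfg.for_stage(self.vdw_form, self.polar_tolerance_scale,
                            self.dihedral_weight_scale)
        if self.vdw_cap is not None:
            out = replace(out, vdw_cap=self.vdw_cap)
        return out


def default_schedule(population_size: int = 50) -> list[StageParams]:
    # early stages additionally soften the short-range clash cap so that
    # sterically frustrated starting poses remain comparable and flexible
    # chains can thread into tight pockets before the 6-12 form hardens
    sched = [
        StageParams("GA1", "4-8", 2.0, 0.25, population_size, vdw_cap=5.0),
        StageParams("GA2", "4-8", 1.5, 0.5, population_size, vdw_cap=20.0),
        StageParams("GA3", "6-12", 1.25, 0.75, population_size),
        StageParams("MC", "6-12", 1.0, 1.0, population_size,
                    mc_temperature=0.5,
                    mutation_widths={"com": 1.0, "euler": 20.0, "dihedral": 20.0}),
        StageParams("MIN", "6-12", 1.0, 1.0, population_size),
    ]
    validate_schedule(sched)
    return sched


def validate_schedule(sched) -> None:
    """Asserts the fixed stage invariants at runtime."""
    by = {s.stage: s for s in sched}
    for name in ("GA1", "GA2"):
        if by[name].vdw_form != "4-8":
            raise ValueError(f"{name} must use the 4-8 vdW form")
    for name in ("GA3", "MC", "MIN"):
        if by[name].vdw_form != "6-12":
            raise ValueError(f"{name} must use the 6-12 vdW form")
    order = ["GA1", "GA2", "GA3", "MC"]
    tols = [by[n].polar_tolerance_scale for n in order]
    dih = [by[n].dihedral_weight_scale for n in order]
    if any(b > a for a, b in zip(tols, tols[1:])):
        raise ValueError("polar tolerance scales must be non-increasing")
    if any(b < a for a, b in zip(dih, dih[1:])):
        raise ValueError("dihedral weight scales must be non-decreasing")
    for name in ("MC", "MIN"):
        if by[name].polar_tolerance_scale != 1.0 or by[name].dihedral_weight_scale != 1.0:
            raise ValueError("all scales must be 1 at MC/MIN")


@dataclass
class DockResult:
    pose: Ligand
    breakdown: ScoreBreakdown
    run_index: int
    converged_generation: int
    rec_dihedrals: np.ndarray | None = None


# ----------------------------------------------------------------------
# GA operators


def initialize_population(n: int, cavity: CavityGrid, lig: Ligand,
                          rec: Receptor, rng, codec: ChromosomeCodec | None = None):
    """Random chromosomes: COM on a random cavity grid point, orientation
    and all dihedral angles uniform over their ranges."""
    if n < 2:
        raise ValueError("population size must be at least 2")
    codec = codec or ChromosomeCodec(lig, rec)
    if codec.tether is None:
        if cavity is None or cavity.n_inside == 0:
            raise ValueError("cannot initialise population: empty cavity")
        pts = cavity.cavity_points
    pop = []
    for _ in range(n):
        nl, nr = codec.n_lig, codec.n_rec
        lig_dih = rng.uniform(-180.0, 180.0, nl)
        rec_dih = rng.uniform(-180.0, 180.0, nr)
        if codec.tether is not None:
            spec = codec.tether.spec
            t = _random_in_ball(rng, spec.trans_tol)
            rv = _random_in_ball(rng, spec.rot_tol)
            pop.append(Chromosome(t, rv, lig_dih, rec_dih))
        else:
            com = pts[rng.integers(len(pts))]
            heading = rng.uniform(-180.0, 180.0)
            attitude = rng.uniform(-90.0, 90.0)
            bank = rng.uniform(-180.0, 180.0)
            pop.append(Chromosome(com, (heading, attitude, bank),
                                  lig_dih, rec_dih))
    return pop


def _random_in_ball(rng, radius):
    if radius <= 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    if n == 0:
        return np.zeros(3)
    r = radius * rng.uniform() ** (1.0 / 3.0)
    return v / n * r


def _dof_kind(i: int, n_lig: int) -> str:
    if i < 3:
        return "com"
    if i < 6:
        return "euler"
    return "dihedral"


def mutate(chrom: Chromosome, widths: dict, rng,
           tether=None) -> Chromosome:
    """Mutate exactly one randomly selected degree of freedom.

    The delta is drawn from a rectangular distribution of the configured
    width; angles are renormalised to (-180, 180].  In tethered mode the
    rigid-body genes are re-clamped to the tether tolerances.
    """
    v = chrom.as_vector()
    n_lig = len(chrom.ligand_dihedrals)
    i = int(rng.integers(chrom.n_dof))
    kind = _dof_kind(i, n_lig)
    w = widths[kind]
    if tether is not None and kind in ("com", "euler"):
        w = min(w, (tether.spec.trans_tol if kind == "com"
                    else tether.spec.rot_tol))
    v[i] += rng.uniform(-w / 2.0, w / 2.0)
    if i >= 6 or (tether is None and i >= 3):
        v[i] = float(_wrap(v[i]))
    out = Chromosome.from_vector(v, n_lig, len(chrom.receptor_dihedrals))
    if tether is not None:
        out.com = _clamp_norm(out.com, tether.spec.trans_tol)
        out.euler = _clamp_norm(out.euler, tether.spec.rot_tol)
    return out


def crossover(a: Chromosome, b: Chromosome, rng) -> Chromosome:
    """Per-gene uniform mix of two parents."""
    va, vb = a.as_vector(), b.as_vector()
    pick = rng.integers(0, 2, size=len(va)).astype(bool)
    return Chromosome.from_vector(np.where(pick, va, vb),
                                  len(a.ligand_dihedrals),
                                  len(a.receptor_dihedrals))


def _rank_select(rng, n: int, cumw=None) -> int:
    """Linear rank selection over a population sorted best-first."""
    if cumw is None:
        w = np.arange(n, 0, -1, dtype=float)
        cumw = np.cumsum(w / w.sum())
    return int(np.searchsorted(cumw, rng.random(), side="right"))


def run_ga_stage(pop, stage: StageParams, scorer, rng, tether=None,
                 convergence_delta: float = 0.1):
    """Steady-state GA with rank selection, uniform crossover, single-DOF
    mutation and elitist replace-worst insertion.

    ``scorer`` maps a chromosome to a score (lower is better).  A generation
    has passed when as many children have been created as the population
    size.  Terminates when the population best improved by less than
    ``convergence_delta`` over the last three generations (tested as soon as
    three generations of history exist), or at ``stage.max_generations``.
    Returns the population sorted best-first (list of (chromosome, score))
    and the per-generation best-score trace.
    """
    import bisect

    if not pop:
        raise ValueError("empty population")
    scored = [(c, scorer(c)) if not isinstance(c, tuple) else c for c in pop]
    scored.sort(key=lambda cs: cs[1])
    chroms = [c for c, _ in scored]
    scores = [s for _, s in scored]
    n = len(chroms)
    w = np.arange(n, 0, -1, dtype=float)
    cumw = np.cumsum(w / w.sum())
    history = [scores[0]]
    for _gen in range(stage.max_generations):
        for _ in range(n):
            pa = chroms[_rank_select(rng, n, cumw)]
            pb = chroms[_rank_select(rng, n, cumw)]
            child = mutate(crossover(pa, pb, rng), stage.mutation_widths,
                           rng, tether)
            s = scorer(child)
            if s < scores[-1]:
                chroms.pop()
                scores.pop()
                k = bisect.bisect_right(scores, s)
                scores.insert(k, s)
                chroms.insert(k, child)
        history.append(scores[0])
        if len(history) >= 4 and history[-4] - history[-1] < convergence_delta:
            break
    return list(zip(chroms, scores)), history


def mc_refine(chrom: Chromosome, stage: StageParams, scorer, rng,
              n_steps: int | None = None, tether=None):
    """Low-temperature Metropolis Monte Carlo; returns the best-seen state,
    so the returned score never exceeds the input score."""
    n_steps = stage.mc_steps if n_steps is None else n_steps
    cur, cur_s = chrom, scorer(chrom)
    best, best_s = cur, cur_s
    t = max(stage.mc_temperature, 0.0)
    for _ in range(n_steps):
        cand = mutate(cur, stage.mutation_widths, rng, tether)
        s = scorer(cand)
        d = s - cur_s
        if d <= 0 or (t > 0 and rng.uniform() < math.exp(-d / t)):
            cur, cur_s = cand, s
            if s < best_s:
                best, best_s = cand, s
    return best, best_s


def simplex_minimize(chrom: Chromosome, scorer, xatol: float = 1e-4,
                     fatol: float = 1e-4, max_evals: int = 2000,
                     n_lig=None, n_rec=None):
    """Nelder-Mead over the chromosome vector; score never increases."""
    from scipy.optimize import minimize

    nl = len(chrom.ligand_dihedrals) if n_lig is None else n_lig
    nr = len(chrom.receptor_dihedrals) if n_rec is None else n_rec
    x0 = chrom.as_vector()
    f0 = scorer(chrom)

    def fun(x):
        return scorer(Chromosome.from_vector(x, nl, nr))

    # initial simplex with per-DOF physical step sizes (A / degrees)
    steps = np.concatenate([np.full(3, 0.3), np.full(3, 5.0),
                            np.full(nl + nr, 5.0)])
    simplex = np.vstack([x0] + [x0 + steps[k] * np.eye(len(x0))[k]
                                for k in range(len(x0))])
    res = minimize(fun, x0, method="Nelder-Mead",
                   options={"xatol": xatol, "fatol": fatol, "adaptive": True,
                            "maxfev": max_evals, "initial_simplex": simplex})
    if res.fun <= f0:
        return Chromosome.from_vector(res.x, nl, nr), float(res.fun)
    return chrom, float(f0)


# ----------------------------------------------------------------------
# full docking pipeline


class _ChromScorer:
    """Chromosome -> total score via codec + PoseScorer; optionally records
    every decoded pose (used to verify tether guarantees)."""

    def __init__(self, codec: ChromosomeCodec, scorer: PoseScorer,
                 record=None):
        self.codec, self.scorer = codec, scorer
        self.record = record
        self.n_evals = 0

    def __call__(self, chrom: Chromosome) -> float:
        lig_coords, rec_coords = self.codec.decode(chrom)
        self.n_evals += 1
        if self.record is not None:
            self.record.append(lig_coords)
        angles = (chrom.ligand_dihedrals if self.codec.tether is None else None)
        return self.scorer.score(lig_coords, rec_coords,
                                 lig_dihedral_angles=angles).total


def _population_size(base: int, codec: ChromosomeCodec) -> int:
    return base + 4 * (codec.n_lig + codec.n_rec)


def dock(lig: Ligand, rec: Receptor, cavity: CavityGrid | None,
         restraints=None, cfg: ScoringConfig | None = None,
         n_runs: int = 50, seed=0, schedule=None, grids=None,
         protocol: str = "dock", pose_record=None,
         run_offset: int = 0) -> list[DockResult]:
    """Multi-run staged docking; results sorted by final total score.

    ``protocol`` may be ``"dock"`` (full GA1..MIN pipeline), ``"minimise"``
    (Simplex from the input pose) or ``"score"`` (score the input pose
    as-is).  ``seed`` may be an int or a sequence of ints; every source of
    randomness derives from it.
    """
    cfg = (cfg or ScoringConfig()).validate()
    tether_ctx = None
    if restraints is not None and getattr(restraints, "tether", None) is not None:
        from . import restraints as rmod

        spec = restraints.tether
        if spec.mapping is not None:
            lig = rmod.prealign(lig, spec.mapping, spec)
            mapping = spec.mapping
        else:
            entries = rmod.match_and_replicate([lig], spec)
            if not entries:
                raise ValueError("ligand does not match the tether SMARTS query")
            lig, mapping = entries[0]
        tether_ctx = make_tether_context(lig, spec, mapping)
    codec = ChromosomeCodec(lig, rec, tether_ctx)
    scorer = PoseScorer(lig, rec, cavity, restraints, cfg, grids)
    cs = _ChromScorer(codec, scorer, pose_record)
    schedule = schedule or default_schedule()
    validate_schedule(schedule)
    stages = {s.stage: s for s in schedule}
    final_cfg = stages["MIN"].apply(cfg)

    if protocol in ("score", "minimise"):
        chrom = codec.encode(lig.molecule.coords)
        scorer.set_config(final_cfg)
        if protocol == "minimise":
            chrom, _ = simplex_minimize(chrom, cs)
        lig_coords, rec_coords = codec.decode(chrom)
        bd = scorer.score(lig_coords, rec_coords)
        pose = lig.with_coords(lig_coords)
        return [DockResult(pose, bd, 0, 0,
                           chrom.receptor_dihedrals.copy() if codec.n_rec else None)]

    base_seed = list(seed) if isinstance(seed, (tuple, list)) else [int(seed)]
    results = []
    for run in range(run_offset, n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(base_seed + [run]))
        pop_n = _population_size(stages["GA1"].population_size, codec)
        scorer.set_config(stages["GA1"].apply(cfg))
        pop = initialize_population(pop_n, cavity, lig, rec, rng, codec)
        gens = 0
        for name in ("GA1", "GA2", "GA3"):
            st = stages[name]
            scorer.set_config(st.apply(cfg))
            pop, hist = run_ga_stage(pop, st, cs, rng, tether_ctx)
            gens += len(hist) - 1
        best = pop[0][0]
        st = stages["MC"]
        scorer.set_config(st.apply(cfg))
        best, _ = mc_refine(best, st, cs, rng, tether=tether_ctx)
        scorer.set_config(final_cfg)
        best, _ = simplex_minimize(best, cs)
        lig_coords, rec_coords = codec.decode(best)
        bd = scorer.score(lig_coords, rec_coords)
        results.append(DockResult(
            lig.with_coords(lig_coords), bd, run, gens,
            best.receptor_dihedrals.copy() if codec.n_rec else None))
    results.sort(key=lambda r: r.breakdown.total)
    return results


# ----------------------------------------------------------------------
# multi-step HTVS protocol


@dataclass
class HtvsLigandResult:
    ligand_index: int
    best_score: float
    best_result: DockResult | None
    runs_done: int
    eliminated_after_stage: int | None  # None = survived the full protocol


def run_htvs(ligands, protocol, rec: Receptor, cavity: CavityGrid,
             restraints=None, cfg: ScoringConfig | None = None,
             seed: int = 0, schedule=None, grids=None):
    """Staged docking with early elimination of poor scorers.

    ``protocol`` is a list of ``(n_runs_cumulative, score_threshold)``
    pairs; thresholds must be strictly decreasing and run counts strictly
    increasing.  After each stage, ligands whose best score so far is above
    the stage threshold are eliminated (the last stage's threshold may be
    None, keeping all remaining ligands).  Returns the per-ligand results
    ranked by best score and the per-stage survivor index lists.
    """
    runs = [p[0] for p in protocol]
    ths = [p[1] for p in protocol if p[1] is not None]
    if any(b <= a for a, b in zip(runs, runs[1:])):
        raise ValueError("protocol run counts must be strictly increasing")
    if any(b >= a for a, b in zip(ths, ths[1:])):
        raise ValueError("protocol thresholds must be strictly decreasing")

    states = []
    for i, lig in enumerate(ligands):
        states.append({"index": i, "lig": lig, "best": None, "runs": 0,
                       "eliminated": None, "results": []})
    survivors = list(range(len(ligands)))
    survivor_history = []
    for k, (cum_runs, threshold) in enumerate(protocol):
        for i in survivors:
            st = states[i]
            # per-run seeds depend only on (seed, ligand, run index), so the
            # staged continuation is identical to one uninterrupted campaign
            extra = dock(st["lig"], rec, cavity, restraints, cfg,
                         n_runs=cum_runs, seed=[seed, i], schedule=schedule,
                         grids=grids, run_offset=st["runs"])
            st["results"] = sorted(st["results"] + extra,
                                   key=lambda r: r.breakdown.total)
            st["runs"] = cum_runs
            st["best"] = st["results"][0]
        if threshold is not None:
            survivors = [i for i in survivors
                         if states[i]["best"].breakdown.total <= threshold]
            for i in range(len(states)):
                if states[i]["eliminated"] is None and i not in survivors \
                        and states[i]["runs"] > 0:
                    states[i]["eliminated"] = k
        survivor_history.append(list(survivors))

    out = []
    for st in states:
        if st["best"] is None:
            continue
        out.append(HtvsLigandResult(st["index"], st["best"].breakdown.total,
                                    st["best"], st["runs"], st["eliminated"]))
    out.sort(key=lambda r: r.best_score)
    return out, survivor_history
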