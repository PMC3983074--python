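"""Chromosome codec, GA operators, MC/Simplex refinement, docking, HTVS."""

import numpy as np
import pytest
from scipy import stats

from gadock.cavity import CavityGrid
from gadock.fixtures import make_redocking_suite, make_toy_ligand
from gadock.model import Receptor
from gadock.search import (Chromosome, ChromosomeCodec, StageParams,
                           default_schedule, dock, initialize_population,
                           mc_refine, mutate, run_ga_stage, run_htvs,
                           simplex_minimize, validate_schedule, crossover)

from conftest import simple_molecule


def box_cavity(center=(0.0, 0.0, 0.0), n=5, spacing=1.0):
    origin = np.asarray(center, dtype=float) - spacing * (n - 1) / 2.0
    return CavityGrid(origin, spacing, np.ones((n, n, n), dtype=bool))


@pytest.fixture(scope="module")
def flexible_system():
    lig = make_toy_ligand(seed=2, n_heavy=6, n_rotatable=2,
                          features=("neutral HBA", "neutral HBD"))
    rec = Receptor(simple_molecule(["C"], [[40.0, 0, 0]], []))
    return lig, rec


class TestCodec:
    def test_identity_chromosome_reproduces_input_pose(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        chrom = codec.encode(lig.molecule.coords)
        pose, _ = codec.decode(chrom)
        assert np.abs(pose - lig.molecule.coords).max() < 1e-6

    def test_com_shift_translates_all_atoms(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        chrom = codec.encode(lig.molecule.coords)
        shifted = chrom.copy()
        shifted.com = chrom.com + np.array([1.0, 0.0, 0.0])
        pose, _ = codec.decode(shifted)
        assert np.abs(pose - lig.molecule.coords - [1.0, 0, 0]).max() < 1e-6

    def test_heading_is_periodic(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        chrom = codec.encode(lig.molecule.coords)
        a, b = chrom.copy(), chrom.copy()
        b.euler = b.euler + np.array([360.0, 0.0, 0.0])
        pa, _ = codec.decode(a)
        pb, _ = codec.decode(b)
        assert np.abs(pa - pb).max() < 1e-9

    def test_round_trip_on_random_chromosomes(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        rng = np.random.default_rng(4)
        for _ in range(10):
            chrom = Chromosome(rng.uniform(-5, 5, 3),
                               (rng.uniform(-179, 179), rng.uniform(-89, 89),
                                rng.uniform(-179, 179)),
                               rng.uniform(-179, 179, codec.n_lig), [])
            pose, _ = codec.decode(chrom)
            pose2, _ = codec.decode(codec.encode(pose))
            assert np.abs(pose - pose2).max() < 1e-6

    def test_dihedral_count_mismatch_raises(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        with pytest.raises(ValueError):
            codec.decode(Chromosome(np.zeros(3), np.zeros(3), [0.0], []))


class TestInitialisation:
    def test_com_on_cavity_grid_points(self, flexible_system):
        lig, rec = flexible_system
        cav = box_cavity()
        rng = np.random.default_rng(0)
        pop = initialize_population(50, cav, lig, rec, rng)
        pts = {tuple(p) for p in cav.cavity_points}
        assert all(tuple(c.com) in pts for c in pop)

    def test_same_seed_identical_population(self, flexible_system):
        lig, rec = flexible_system
        cav = box_cavity()
        a = initialize_population(20, cav, lig, rec, np.random.default_rng(9))
        b = initialize_population(20, cav, lig, rec, np.random.default_rng(9))
        for x, y in zip(a, b):
            assert np.array_equal(x.as_vector(), y.as_vector())

    def test_dihedral_angles_uniform(self, flexible_system):
        lig, rec = flexible_system
        cav = box_cavity()
        pop = initialize_population(10000, cav, lig, rec,
                                    np.random.default_rng(1))
        angles = np.array([c.ligand_dihedrals[0] for c in pop])
        p = stats.kstest((angles + 180.0) / 360.0, "uniform").pvalue
        assert p > 0.01

    def test_empty_cavity_raises(self, flexible_system):
        lig, rec = flexible_system
        with pytest.raises(ValueError):
            initialize_population(10, None, lig, rec, np.random.default_rng(0))


class TestMutation:
    def test_exactly_one_dof_changes(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        chrom = codec.encode(lig.molecule.coords)
        rng = np.random.default_rng(3)
        widths = {"com": 2.0, "euler": 30.0, "dihedral": 30.0}
        for _ in range(50):
            out = mutate(chrom, widths, rng)
            assert (chrom.as_vector() != out.as_vector()).sum() == 1

    def test_deltas_uniform_on_width(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        chrom = codec.encode(lig.molecule.coords)
        rng = np.random.default_rng(5)
        widths = {"com": 2.0, "euler": 2.0, "dihedral": 2.0}
        deltas = []
        for _ in range(20000):
            out = mutate(chrom, widths, rng)
            d = out.as_vector() - chrom.as_vector()
            i = np.nonzero(d)[0]
            if len(i) == 1 and i[0] < 3:  # COM coordinate: no wrapping
                deltas.append(d[i[0]])
        p = stats.kstest((np.array(deltas) + 1.0) / 2.0, "uniform").pvalue
        assert p > 0.01

    def test_zero_width_limit_is_identity(self, flexible_system):
        lig, rec = flexible_system
        codec = ChromosomeCodec(lig, rec)
        chrom = codec.encode(lig.molecule.coords)
        widths = {"com": 1e-12, "euler": 1e-12, "dihedral": 1e-12}
        out = mutate(chrom, widths, np.random.default_rng(0))
        assert np.abs(out.as_vector() - chrom.as_vector()).max() < 1e-12


class BowlScorer:
    """Analytic quadratic bowl over the COM genes: S = |com - target|^2 - 10."""

    def __init__(self, target=(0.7, -0.3, 0.2)):
        self.target = np.asarray(target)

    def __call__(self, chrom):
        d = chrom.com - self.target
        return float(d @ d) - 10.0


class TestGA:
    def make_pop(self, n, rng, spread=3.0):
        return [Chromosome(rng.uniform(-spread, spread, 3), np.zeros(3), [], [])
                for _ in range(n)]

    def test_uniform_population_terminates_within_three_generations(self):
        scorer = BowlScorer()
        optimum = Chromosome(np.array(scorer.target), np.zeros(3), [], [])
        pop = [optimum.copy() for _ in range(20)]
        stage = StageParams("GA3", "6-12", 1.0, 1.0, 20)
        _, history = run_ga_stage(pop, stage, scorer, np.random.default_rng(0))
        assert len(history) - 1 <= 3

    def test_best_score_trace_is_non_increasing(self):
        rng = np.random.default_rng(7)
        pop = self.make_pop(30, rng)
        stage = StageParams("GA1", "4-8", 2.0, 0.25, 30)
        _, history = run_ga_stage(pop, stage, BowlScorer(), rng)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_ga_approaches_analytic_minimum(self):
        rng = np.random.default_rng(11)
        pop = self.make_pop(40, rng)
        stage = StageParams("GA3", "6-12", 1.0, 1.0, 40,
                            mutation_widths={"com": 0.5, "euler": 10.0,
                                             "dihedral": 10.0})
        out, _ = run_ga_stage(pop, stage, BowlScorer(), rng)
        assert out[0][1] < -10.0 + 0.25 ** 2

    def test_ga_beats_equal_budget_random_search(self):
        wins = 0
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            scorer = BowlScorer(rng.uniform(-2, 2, 3))
            pop = self.make_pop(30, rng)
            counting = _CountingScorer(scorer)
            out, _ = run_ga_stage(pop, StageParams("GA3", "6-12", 1.0, 1.0, 30),
                                  counting, rng)
            budget = counting.n
            rand_best = min(scorer(c) for c in self.make_pop(budget, rng))
            if out[0][1] <= rand_best:
                wins += 1
        assert wins >= 8


class _CountingScorer:
    def __init__(self, inner):
        self.inner, self.n = inner, 0

    def __call__(self, c):
        self.n += 1
        return self.inner(c)


class TestRefinement:
    def test_mc_zero_temperature_never_accepts_uphill(self):
        scorer = BowlScorer()
        start = Chromosome(np.array([2.0, 2.0, 2.0]), np.zeros(3), [], [])
        stage = StageParams("MC", "6-12", 1.0, 1.0, mc_temperature=0.0,
                            mc_steps=200)
        trace = []

        def tracking(c):
            s = scorer(c)
            trace.append(s)
            return s

        best, bs = mc_refine(start, stage, tracking, np.random.default_rng(0))
        assert bs <= scorer(start)

    def test_mc_returns_best_seen(self):
        scorer = BowlScorer()
        start = Chromosome(np.array([1.0, 0.0, 0.0]), np.zeros(3), [], [])
        stage = StageParams("MC", "6-12", 1.0, 1.0, mc_temperature=0.5,
                            mc_steps=300)
        best, bs = mc_refine(start, stage, scorer, np.random.default_rng(1))
        assert bs <= scorer(start)

    def test_mc_improves_near_optimum_on_average(self):
        scorer = BowlScorer()
        stage = StageParams("MC", "6-12", 1.0, 1.0, mc_temperature=0.1,
                            mc_steps=100,
                            mutation_widths={"com": 0.3, "euler": 5.0,
                                             "dihedral": 5.0})
        gains = []
        for seed in range(40):
            start = Chromosome(np.array([0.9, -0.1, 0.4]), np.zeros(3), [], [])
            s0 = scorer(start)
            _, bs = mc_refine(start, stage, scorer, np.random.default_rng(seed))
            gains.append(s0 - bs)
        assert np.mean(gains) > 0

    def test_simplex_fixed_point_at_optimum(self):
        scorer = BowlScorer()
        start = Chromosome(np.array(scorer.target), np.zeros(3), [], [])
        out, s = simplex_minimize(start, scorer)
        assert s <= scorer(start) + 1e-12

    def test_simplex_reaches_analytic_minimum(self):
        scorer = BowlScorer()
        rng = np.random.default_rng(2)
        for _ in range(5):
            start = Chromosome(rng.uniform(-3, 3, 3), np.zeros(3), [], [])
            _, s = simplex_minimize(start, scorer)
            assert abs(s - (-10.0)) < 1e-3


class TestSchedule:
    def test_default_schedule_satisfies_invariants(self):
        validate_schedule(default_schedule())

    def test_bad_schedules_rejected(self):
        sched = default_schedule()
        sched[0].vdw_form = "6-12"
        with pytest.raises(ValueError):
            validate_schedule(sched)
        sched = default_schedule()
        sched[3].polar_tolerance_scale = 1.5
        with pytest.raises(ValueError):
            validate_schedule(sched)


@pytest.fixture(scope="module")
def system():
    return make_redocking_suite(1, seed=21, rotor_counts=[1], ref_runs=0)[0]


class TestDocking:

    def test_single_run_yields_single_result(self, system):
        res = dock(system.ligand, system.receptor, system.cavity, n_runs=1,
                   seed=5)
        assert len(res) == 1
        assert res[0].run_index == 0

    def test_best_score_non_increasing_in_run_count(self, system):
        res5 = dock(system.ligand, system.receptor, system.cavity, n_runs=5,
                    seed=5)
        res2 = dock(system.ligand, system.receptor, system.cavity, n_runs=2,
                    seed=5)
        assert res5[0].breakdown.total <= res2[0].breakdown.total

    def test_dock_deterministic_under_master_seed(self, system):
        a = dock(system.ligand, system.receptor, system.cavity, n_runs=2, seed=8)
        b = dock(system.ligand, system.receptor, system.cavity, n_runs=2, seed=8)
        for x, y in zip(a, b):
            assert x.breakdown.total == y.breakdown.total
            assert np.array_equal(x.pose.molecule.coords, y.pose.molecule.coords)

    def test_score_protocol_returns_input_pose_score(self, system):
        res = dock(system.ligand, system.receptor, system.cavity,
                   protocol="score")
        assert len(res) == 1
        assert np.abs(res[0].pose.molecule.coords
                      - system.ligand.molecule.coords).max() < 1e-6

    def test_minimise_protocol_does_not_worsen_the_score(self, system):
        scored = dock(system.ligand, system.receptor, system.cavity,
                      protocol="score")[0]
        minimised = dock(system.ligand, system.receptor, system.cavity,
                         protocol="minimise")[0]
        assert minimised.breakdown.total <= scored.breakdown.total + 1e-9


@pytest.fixture(scope="module")
def library():
    suite = make_redocking_suite(1, seed=31, rotor_counts=[1], ref_runs=0)
    cx = suite[0]
    ligs = [cx.ligand]
    for k, rot in enumerate((0, 1)):
        feats = ("neutral HBA",) if rot == 0 else ("neutral HBD",)
        ligs.append(make_toy_ligand(seed=50 + k, n_heavy=4,
                                    n_rotatable=rot, features=feats))
    return cx, ligs


class TestHtvs:

    def test_malformed_protocols_rejected(self, library):
        cx, ligs = library
        with pytest.raises(ValueError):
            run_htvs(ligs, [(5, -20.0), (3, -25.0)], cx.receptor, cx.cavity)
        with pytest.raises(ValueError):
            run_htvs(ligs, [(5, -20.0), (10, -15.0)], cx.receptor, cx.cavity)

    def test_one_stage_protocol_reproduces_plain_docking(self, library):
        cx, ligs = library
        results, _ = run_htvs(ligs[:2], [(2, None)], cx.receptor, cx.cavity,
                              seed=4)
        for r in results:
            direct = dock(ligs[r.ligand_index], cx.receptor, cx.cavity,
                          n_runs=2, seed=[4, r.ligand_index])
            assert r.best_score == direct[0].breakdown.total

    def test_survivors_match_thresholds_and_are_nested(self, library):
        cx, ligs = library
        results, history = run_htvs(ligs, [(1, -5.0), (2, -8.0), (3, None)],
                                    cx.receptor, cx.cavity, seed=4)
        assert all(set(b) <= set(a) for a, b in zip(history, history[1:]))
        # recompute stage-1 survivors from scratch
        expected = []
        for i, lig in enumerate(ligs):
            best = dock(lig, cx.receptor, cx.cavity, n_runs=1,
                        seed=[4, i])[0].breakdown.total
            if best <= -5.0:
                expected.append(i)
        assert history[0] == expected
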