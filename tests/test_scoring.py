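"""The composite scoring function: closed forms, SASA, grids, invariants."""

import math

import numpy as np
import pytest

from gadock.cavity import map_reference_ligand
from gadock.fixtures import make_redocking_suite, make_toy_ligand
from gadock.model import Molecule, Receptor, euler_to_matrix
from gadock.params import ScoringConfig, load_param_table, vdw_radius
from gadock.scoring import (PoseScorer, build_vdw_grids, desolvation_score,
                            hasel_sasa, ligand_dihedral_energy,
                            polar_pair_energy, score_pose, vdw_pair_energy)
from gadock.torsions import make_ligand

from conftest import simple_molecule


class TestVdwClosedForms:
    @pytest.mark.parametrize("form,m", [("6-12", 6), ("4-8", 4)])
    def test_minimum_at_r0(self, form, m):
        assert vdw_pair_energy(3.4, 3.4, 0.2, form) == pytest.approx(-0.2, abs=1e-12)
        # derivative check: nearby points are higher
        for dr in (-1e-4, 1e-4):
            assert vdw_pair_energy(3.4 + dr, 3.4, 0.2, form) > -0.2

    @pytest.mark.parametrize("form,m", [("6-12", 6), ("4-8", 4)])
    def test_analytic_zero_crossing(self, form, m):
        r_zero = 3.4 * 2.0 ** (-1.0 / m)
        assert abs(vdw_pair_energy(r_zero, 3.4, 0.2, form)) < 1e-9

    def test_limits_and_errors(self):
        assert vdw_pair_energy(100.0, 3.4, 0.2, "6-12") == pytest.approx(0.0, abs=1e-8)
        assert vdw_pair_energy(0.1, 3.4, 0.2, "6-12", cap=100.0) == 100.0
        with pytest.raises(ValueError):
            vdw_pair_energy(0.0, 3.4, 0.2, "6-12")

    def test_kernel_matches_closed_form(self):
        from gadock._kernels import vdw_sum

        rng = np.random.default_rng(0)
        lig = rng.uniform(-3, 3, (5, 3))
        rec = rng.uniform(-3, 3, (7, 3))
        r0 = rng.uniform(3.0, 4.0, (5, 7))
        eps = rng.uniform(0.05, 0.3, (5, 7))
        for form in ("6-12", "4-8"):
            m = 6 if form == "6-12" else 4
            direct = 0.0
            for i in range(5):
                for j in range(7):
                    r = np.linalg.norm(lig[i] - rec[j])
                    direct += float(vdw_pair_energy(r, r0[i, j], eps[i, j],
                                                    form, 100.0))
            assert vdw_sum(lig, rec, r0, eps, m, 100.0) == pytest.approx(direct, abs=1e-9)


class TestPolarTerm:
    def ideal_geometry(self):
        p = load_param_table()["polar"]
        d = sum(p["distance_window"]) / 2.0
        D = np.array([0.0, 0, 0])
        H = np.array([1.0, 0, 0])
        A = np.array([d, 0.0, 0.0])
        R = np.array([d + 1.4, 0.0, 0.0])
        return D, H, A, R

    def test_ideal_geometry_scores_minus_w(self):
        D, H, A, R = self.ideal_geometry()
        cfg = ScoringConfig()
        w = load_param_table()["polar"]["well_depth"]
        assert polar_pair_energy(D, H, A, R, cfg) == pytest.approx(-w)

    def test_beyond_distance_window_plus_tolerance_is_zero(self):
        D, H, A, R = self.ideal_geometry()
        cfg = ScoringConfig()
        hi = load_param_table()["polar"]["distance_window"][1]
        tol = cfg.polar_distance_tolerance
        far = np.array([hi + tol + 0.05, 0.0, 0.0])
        assert polar_pair_energy(D, H, far, far + [1.4, 0, 0], cfg) == 0.0

    def test_same_class_repulsive_under_sf3_only(self):
        D, H, A, R = self.ideal_geometry()
        sf3 = ScoringConfig.sf3()
        e = polar_pair_energy(D, None, A, None, sf3, same_class=True)
        assert e > 0
        att_only = ScoringConfig(polar_mode="attractive-only")
        assert polar_pair_energy(D, None, A, None, att_only, same_class=True) == 0.0

    def test_charged_partners_scale_the_well(self):
        D, H, A, R = self.ideal_geometry()
        cfg = ScoringConfig()
        p = load_param_table()["polar"]
        e = polar_pair_energy(D, H, A, R, cfg, donor_charged=True)
        assert e == pytest.approx(-p["well_depth"] * p["charged_multiplier"])

    def test_relaxed_tolerance_widens_the_ramp(self):
        D, H, A, R = self.ideal_geometry()
        hi = load_param_table()["polar"]["distance_window"][1]
        cfg = ScoringConfig()
        stretched = np.array([hi + 0.8, 0.0, 0.0])
        tight = polar_pair_energy(D, H, stretched, stretched + [1.4, 0, 0], cfg)
        relaxed_cfg = ScoringConfig(polar_tolerance_scale=2.0)
        relaxed = polar_pair_energy(D, H, stretched, stretched + [1.4, 0, 0],
                                    relaxed_cfg)
        assert relaxed < tight <= 0.0


class TestHaselSasa:
    def test_isolated_atom_is_exact(self):
        a = hasel_sasa(["C"], np.zeros((1, 3)))
        r = vdw_radius("C") + 1.4
        assert a[0] == pytest.approx(4 * math.pi * r * r, rel=1e-12)

    def test_two_atom_symmetry(self):
        a = hasel_sasa(["C", "C"], [[0.0, 0, 0], [1.5, 0, 0]], [(0, 1)])
        assert a[0] == pytest.approx(a[1])

    def test_fully_caged_atom_is_nearly_buried(self):
        from gadock.fixtures import _fibonacci_sphere

        centers = np.vstack([np.zeros(3), _fibonacci_sphere(40) * 1.9])
        a = hasel_sasa(["C"] * 41, centers)
        S = 4 * math.pi * (vdw_radius("C") + 1.4) ** 2
        assert a[0] < 0.05 * S

    def test_correlates_with_sphere_sampling_oracle(self):
        from conftest import smiles_to_sdf_text  # noqa: F401  (same env)

        rng = np.random.default_rng(0)
        approx_all, exact_all = [], []
        mols = []
        k = 0
        while len(mols) < 6:
            k += 1
            try:
                mols.append(make_toy_ligand(
                    seed=k, n_heavy=6, n_rotatable=min(k + 1, 3),
                    features=("neutral HBA", "neutral HBD")))
            except ValueError:
                continue
        for lig in mols:
            m = lig.molecule
            approx = hasel_sasa(m.elements, m.coords,
                                [(i, j) for i, j, _ in m.bonds])
            exact = numerical_sasa(m.elements, m.coords)
            approx_all.extend(approx)
            exact_all.extend(exact)
        # a small homogeneous panel: the full 20-molecule check lives in the
        # acceptance suite at its stated tolerance
        r = np.corrcoef(approx_all, exact_all)[0, 1]
        assert r > 0.9

    def test_distance_floor_handles_coincident_atoms(self):
        a = hasel_sasa(["C", "C"], np.zeros((2, 3)))
        assert np.all(np.isfinite(a)) and np.all(a >= 0)


def numerical_sasa(elements, coords, n_points: int = 960, r_solv: float = 1.4):
    """Shrake-Rupley style sphere-sampling SASA oracle."""
    from gadock.fixtures import _fibonacci_sphere

    coords = np.asarray(coords)
    radii = np.array([vdw_radius(e) + r_solv for e in elements])
    sphere = _fibonacci_sphere(n_points)
    out = []
    for i in range(len(elements)):
        pts = coords[i] + sphere * radii[i]
        free = np.ones(n_points, dtype=bool)
        for j in range(len(elements)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        out.append(4 * math.pi * radii[i] ** 2 * free.mean())
    return np.array(out)


class TestDesolvationAndTorsion:
    def test_far_apart_ligand_has_zero_desolvation(self):
        lig = make_ligand(simple_molecule(["C"], [[500.0, 0, 0]], []))
        rec = Receptor(simple_molecule(["C", "O"], [[0.0, 0, 0], [3.0, 0, 0]],
                                       [(0, 1, 1)]))
        assert desolvation_score(lig.molecule.coords, lig, rec) == pytest.approx(0.0, abs=1e-9)

    def test_buried_apolar_atom_is_favourable(self):
        from gadock.fixtures import _fibonacci_sphere

        lig = make_ligand(simple_molecule(["C"], [[0.0, 0, 0]], []))
        shell = _fibonacci_sphere(20) * 3.8
        rec = Receptor(simple_molecule(["C"] * 20, shell, []))
        assert desolvation_score(lig.molecule.coords, lig, rec) < 0.0

    def test_determinism(self):
        lig = make_ligand(simple_molecule(["C"], [[1.0, 2, 3]], []))
        rec = Receptor(simple_molecule(["C"], [[4.0, 2, 3]], []))
        a = desolvation_score(lig.molecule.coords, lig, rec)
        b = desolvation_score(lig.molecule.coords, lig, rec)
        assert a == b

    def test_torsion_minimum_at_anti_and_scale(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCCC", name="butane")
        from gadock.model import set_dihedral

        dih = lig.rotatable_dihedrals[0]
        cfg = ScoringConfig()
        anti = ligand_dihedral_energy(lig, cfg, set_dihedral(lig.molecule.coords, dih, 180.0))
        gauche = ligand_dihedral_energy(lig, cfg, set_dihedral(lig.molecule.coords, dih, 60.0))
        ecl = ligand_dihedral_energy(lig, cfg, set_dihedral(lig.molecule.coords, dih, 0.0))
        assert anti == pytest.approx(0.0, abs=1e-9)
        assert gauche == pytest.approx(0.0, abs=1e-9)
        assert ecl > anti
        zero = ScoringConfig(dihedral_weight_scale=0.0)
        assert ligand_dihedral_energy(lig, zero, lig.molecule.coords) == 0.0


@pytest.fixture(scope="module")
def toy_complex():
    return make_redocking_suite(1, seed=9, rotor_counts=[2], ref_runs=0)[0]


class TestScorePose:
    def test_far_pose_scores_zero(self, toy_complex):
        cx = toy_complex
        far = cx.ligand.with_coords(cx.ligand.molecule.coords + 500.0)
        bd = score_pose(far, cx.receptor)
        assert bd.inter == pytest.approx(0.0, abs=1e-6)
        assert bd.intra == pytest.approx(0.0, abs=1e-9)
        assert bd.total == pytest.approx(0.0, abs=1e-6)

    def test_intra_zero_at_input_conformation(self, toy_complex):
        cx = toy_complex
        bd = score_pose(cx.ligand, cx.receptor, cx.cavity)
        assert bd.intra == pytest.approx(0.0, abs=1e-9)

    def test_rigid_ligand_intra_always_zero(self):
        lig = make_toy_ligand(seed=1, n_heavy=3, n_rotatable=0,
                              features=("neutral HBA",))
        rec = Receptor(simple_molecule(["C"], [[8.0, 0, 0]], []))
        rng = np.random.default_rng(0)
        scorer = PoseScorer(lig, rec)
        for _ in range(5):
            R = euler_to_matrix(*rng.uniform(-180, 180, 3))
            coords = lig.molecule.coords @ R.T + rng.uniform(-4, 4, 3)
            assert scorer.intra(coords) == 0.0

    def test_total_is_weighted_sum_of_components(self, toy_complex):
        cx = toy_complex
        cfg = ScoringConfig()
        cfg.weights.update({"inter": 1.3, "intra": 0.7, "site": 1.1,
                            "restraint": 2.0})
        bd = score_pose(cx.ligand, cx.receptor, cx.cavity, cfg=cfg)
        expected = (1.3 * bd.inter + 0.7 * bd.intra + 1.1 * bd.site
                    + 2.0 * bd.restraint)
        assert bd.total == pytest.approx(expected, abs=1e-9)

    def test_pure_function_bit_identical(self, toy_complex):
        cx = toy_complex
        a = score_pose(cx.ligand, cx.receptor, cx.cavity)
        b = score_pose(cx.ligand, cx.receptor, cx.cavity)
        assert a.total == b.total and a.sub_terms == b.sub_terms

    def test_rigid_motion_invariance(self, toy_complex):
        cx = toy_complex
        R = euler_to_matrix(25.0, -40.0, 10.0)
        t = np.array([3.0, -2.0, 7.0])
        lig2 = cx.ligand.with_coords(cx.ligand.molecule.coords @ R.T + t)
        rm2 = cx.receptor.molecule.copy()
        rm2.coords = cx.receptor.molecule.coords @ R.T + t
        rec2 = Receptor(rm2, cx.receptor.flexible_dihedrals)
        a = score_pose(cx.ligand, cx.receptor)
        b = score_pose(lig2, rec2)
        assert b.total == pytest.approx(a.total, abs=1e-6)
        assert b.inter == pytest.approx(a.inter, abs=1e-6)
        assert b.intra == pytest.approx(a.intra, abs=1e-6)


class TestVdwGrids:
    def test_lattice_point_matches_direct_sum_exactly(self, toy_complex):
        cx = toy_complex
        grids = build_vdw_grids(cx.receptor, cx.cavity, spacing=0.5,
                                elements=("C",))
        from gadock.scoring import _mix

        rm = cx.receptor.molecule
        k = (3, 4, 5)
        p = grids.origin + np.array(k) * grids.spacing
        direct = 0.0
        for j in range(rm.n_atoms):
            r0, eps = _mix("C", rm.elements[j])
            r = max(np.linalg.norm(p - rm.coords[j]), 1e-6)
            direct += float(vdw_pair_energy(r, r0, eps, "6-12", 100.0))
        assert grids.values["C"][k] == pytest.approx(direct, abs=1e-9)

    def test_empty_receptor_grids_are_zero_beyond_range(self):
        rec = Receptor(simple_molecule(["C"], [[1000.0, 0, 0]], []))
        lig = make_ligand(simple_molecule(["C"], [[0.0, 0, 0]], []))
        cav = map_reference_ligand(rec, lig, 3.0, 0.5)
        grids = build_vdw_grids(rec, cav, spacing=0.5, elements=("C",))
        assert np.abs(grids.values["C"]).max() < 1e-6

    def test_out_of_lattice_query_raises(self, toy_complex):
        cx = toy_complex
        grids = build_vdw_grids(cx.receptor, cx.cavity, spacing=0.5,
                                elements=("C",))
        with pytest.raises(ValueError):
            grids.interpolate("C", np.array([[1e4, 0.0, 0.0]]))

    def test_missing_grids_in_grid_mode_raises(self, toy_complex):
        cx = toy_complex
        scorer = PoseScorer(cx.ligand, cx.receptor)
        with pytest.raises(ValueError):
            scorer.inter_vdw(cx.ligand.molecule.coords, use_grids=True)
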