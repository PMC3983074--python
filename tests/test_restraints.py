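"""Pharmacophore, tether, cavity-containment and distance restraints."""

import math

import numpy as np
import pytest

from gadock.cavity import CavityGrid
from gadock.model import Receptor
from gadock.restraints import (DistanceRestraint, PharmacophoreRestraint,
                               RestraintSet, TetherSpec, cavity_penalty,
                               detect_features, match_and_replicate,
                               nmr_distance_penalty, parse_restraint_file,
                               pharmacophore_penalty, prealign,
                               screen_ligand_features, tether_violation)

from conftest import simple_molecule


class TestFeatureDetection:
    def test_benzene_features(self, ligand_from_smiles):
        lig = ligand_from_smiles("c1ccccc1", name="benzene")
        f = detect_features(lig)
        assert len(f["hydrophobic aromatic"]) == 1
        assert len(f["any heavy atom"]) == 6
        assert len(f["hydrophobic"]) == 6
        assert len(f["hydrophobic aliphatic"]) == 0
        assert len(f["neutral HBA"]) == len(f["neutral HBD"]) == 0
        centroid = lig.molecule.coords[lig.molecule.heavy_mask].mean(axis=0)
        assert np.linalg.norm(f["hydrophobic aromatic"][0] - centroid) < 1e-9

    def test_acetate_negative_oxygens(self, ligand_from_smiles):
        lig = ligand_from_smiles("CC(=O)[O-]", name="acetate")
        f = detect_features(lig)
        assert len(f["negative"]) == 2
        assert len(f["neutral HBA"]) == 0  # charged acceptors are not neutral

    def test_methane_only_heavy_atom_feature(self, ligand_from_smiles):
        lig = ligand_from_smiles("C", name="methane")
        f = detect_features(lig)
        assert len(f["any heavy atom"]) == 1
        assert all(len(f[t]) == 0 for t in
                   ("neutral HBA", "neutral HBD", "negative", "positive",
                    "hydrophobic aromatic"))


class TestPharmacophorePenalty:
    def feats_at(self, *pts):
        return {"neutral HBA": np.array(pts).reshape(-1, 3)}

    def test_zero_inside_sphere(self):
        rs = RestraintSet([PharmacophoreRestraint("neutral HBA",
                                                  (0, 0, 0), 1.5)])
        assert pharmacophore_penalty(self.feats_at([1.0, 0, 0]), rs) == 0.0

    def test_quadratic_outside_surface(self):
        rs = RestraintSet([PharmacophoreRestraint("neutral HBA",
                                                  (0, 0, 0), 1.0)])
        pen = pharmacophore_penalty(self.feats_at([3.0, 0, 0]), rs)
        assert pen == pytest.approx(4.0)   # (3.0 - 1.0)^2 with W = 1

    def test_n_opt_selects_k_smallest(self):
        phs = [PharmacophoreRestraint("neutral HBA", c, 1.0, mandatory=False)
               for c in ([1.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0])]
        rs = RestraintSet(phs, n_opt=2)
        feats = self.feats_at([1.0, 0, 0])
        # distances to surfaces: 0, 0, 2 -> penalties 0, 0, 4; two smallest sum 0
        assert pharmacophore_penalty(feats, rs) == pytest.approx(0.0)
        rs3 = RestraintSet(phs, n_opt=3)
        assert pharmacophore_penalty(feats, rs3) == pytest.approx(4.0)

    def test_monotone_in_n_opt(self):
        rng = np.random.default_rng(0)
        phs = [PharmacophoreRestraint("neutral HBA", rng.uniform(-4, 4, 3),
                                      0.5, mandatory=False) for _ in range(5)]
        feats = self.feats_at([0.0, 0, 0])
        vals = [pharmacophore_penalty(feats, RestraintSet(phs, n_opt=k))
                for k in range(6)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_missing_feature_type_is_infinite_with_warning(self):
        rs = RestraintSet([PharmacophoreRestraint("positive", (0, 0, 0), 1.0)])
        with pytest.warns(UserWarning):
            assert pharmacophore_penalty({"positive": np.zeros((0, 3))},
                                         rs) == math.inf

    def test_restraint_file_round_trip(self, tmp_path):
        p = tmp_path / "ph4.txt"
        p.write_text("NOPT 1\n"
                     "0.0 0.0 0.0 1.5 HBA MANDATORY\n"
                     "1.0 2.0 3.0 2.0 HBD OPTIONAL\n"
                     "4.0 4.0 4.0 1.0 ARO OPTIONAL\n")
        rs = parse_restraint_file(p)
        assert rs.n_opt == 1
        assert [r.mandatory for r in rs.pharmacophores] == [True, False, False]
        assert rs.pharmacophores[2].feature_type == "hydrophobic aromatic"


class TestScreening:
    def test_ligand_without_donor_fails_mandatory_hbd(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCC", name="propane")
        rs = RestraintSet([PharmacophoreRestraint("neutral HBD", (0, 0, 0), 1.0)])
        assert not screen_ligand_features(lig, rs)

    def test_ligand_with_donor_passes(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCO", name="ethanol")
        rs = RestraintSet([PharmacophoreRestraint("neutral HBD", (0, 0, 0), 1.0)])
        assert screen_ligand_features(lig, rs)

    def test_optional_best_case_assignment(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCOC", name="ether")  # HBA only
        phs = [PharmacophoreRestraint("neutral HBA", (0, 0, 0), 1.0, False),
               PharmacophoreRestraint("negative", (0, 0, 0), 1.0, False)]
        assert screen_ligand_features(lig, RestraintSet(phs, n_opt=1))
        assert not screen_ligand_features(lig, RestraintSet(phs, n_opt=2))


class TestTether:
    def test_single_match_single_entry(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCCO", name="propanol")
        from rdkit import Chem

        ref = lig.molecule.coords[:3]
        spec = TetherSpec("CCO", ref)
        entries = match_and_replicate([lig], spec)
        assert len(entries) == 1

    def test_non_matching_ligand_dropped_and_logged(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCC", name="propane")
        spec = TetherSpec("O=C", np.zeros((2, 3)))
        log = []
        assert match_and_replicate([lig], spec, log) == []
        assert log and log[0][1] == "no-substructure-match"

    def test_invalid_smarts_raises_before_docking(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCC", name="propane")
        with pytest.raises(ValueError, match="SMARTS"):
            match_and_replicate([lig], TetherSpec("(((", np.zeros((3, 3))))

    def test_two_orientations_of_a_symmetric_match(self, ligand_from_smiles):
        # para-disubstituted-benzene query on a ligand whose two substituents
        # differ: the two flip orientations are genuinely distinct placements
        lig = ligand_from_smiles("Oc1ccc(N)cc1", name="aminophenol")
        from rdkit import Chem

        from gadock.restraints import _rdkit_mol

        smarts = "[!#1]c1ccc([!#1])cc1"
        rd = _rdkit_mol(lig.molecule)
        q = Chem.MolFromSmarts(smarts)
        mapping = rd.GetSubstructMatch(q)
        spec = TetherSpec(smarts, lig.molecule.coords[list(mapping)])
        entries = match_and_replicate([lig], spec)
        assert len(entries) == 2

    def test_fully_symmetric_molecule_collapses_to_one_entry(
            self, ligand_from_smiles):
        lig = ligand_from_smiles("Cc1ccc(C)cc1", name="para-xylene")
        from gadock.restraints import _rdkit_mol
        from rdkit import Chem

        rd = _rdkit_mol(lig.molecule)
        mapping = rd.GetSubstructMatch(Chem.MolFromSmarts("Cc1ccc(C)cc1"))
        spec = TetherSpec("Cc1ccc(C)cc1", lig.molecule.coords[list(mapping)])
        assert len(match_and_replicate([lig], spec)) == 1

    def test_prealign_is_identity_when_already_aligned(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCCO", name="propanol")
        mapping = (0, 1, 2, 3)
        spec = TetherSpec("CCCO", lig.molecule.coords[list(mapping)])
        out = prealign(lig, mapping, spec)
        assert np.abs(out.molecule.coords - lig.molecule.coords).max() < 1e-9

    def test_prealign_matches_quaternion_oracle(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCCO", name="propanol")
        mapping = [0, 1, 2, 3]
        from gadock.model import euler_to_matrix

        R = euler_to_matrix(90.0, 15.0, -30.0)
        rotated = lig.with_coords(lig.molecule.coords @ R.T + [4.0, -1.0, 2.0])
        spec = TetherSpec("CCCO", lig.molecule.coords[mapping])
        out = prealign(rotated, mapping, spec)
        achieved = _rmsd(out.molecule.coords[mapping], spec.reference_coords)
        oracle = _quaternion_min_rmsd(rotated.molecule.coords[mapping],
                                      spec.reference_coords)
        assert abs(achieved - oracle) < 1e-6

    def test_prealign_under_determined_raises(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCCO", name="propanol")
        spec = TetherSpec("CC", lig.molecule.coords[:2])
        with pytest.raises(ValueError):
            prealign(lig, (0, 1), spec)

    def test_tether_violation_zero_at_prealigned_pose(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCCO", name="propanol")
        mapping = (0, 1, 2, 3)
        spec = TetherSpec("CCCO", lig.molecule.coords[list(mapping)])
        t, r = tether_violation(lig, spec, mapping)
        assert t == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(0.0, abs=1e-4)

    def test_tether_violation_reports_translation(self, ligand_from_smiles):
        lig = ligand_from_smiles("CCCO", name="propanol")
        mapping = (0, 1, 2, 3)
        spec = TetherSpec("CCCO", lig.molecule.coords[list(mapping)])
        moved = lig.with_coords(lig.molecule.coords + [0.05, 0.0, 0.0])
        t, r = tether_violation(moved, spec, mapping)
        assert t == pytest.approx(0.05, abs=1e-9)
        assert r == pytest.approx(0.0, abs=1e-4)


def _rmsd(a, b):
    return float(np.sqrt(np.mean(((a - b) ** 2).sum(axis=1))))


def _quaternion_min_rmsd(mob, ref):
    """Independent superposition oracle (Horn quaternion method)."""
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    P, Q = mob - mc, ref - rc
    M = P.T @ Q
    K = np.array([
        [M[0, 0] + M[1, 1] + M[2, 2], M[1, 2] - M[2, 1],
         M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]],
        [M[1, 2] - M[2, 1], M[0, 0] - M[1, 1] - M[2, 2],
         M[0, 1] + M[1, 0], M[2, 0] + M[0, 2]],
        [M[2, 0] - M[0, 2], M[0, 1] + M[1, 0],
         -M[0, 0] + M[1, 1] - M[2, 2], M[1, 2] + M[2, 1]],
        [M[0, 1] - M[1, 0], M[2, 0] + M[0, 2],
         M[1, 2] + M[2, 1], -M[0, 0] - M[1, 1] + M[2, 2]]])
    lam = np.linalg.eigvalsh(K).max()
    msd = max(0.0, ((P ** 2).sum() + (Q ** 2).sum() - 2 * lam) / len(mob))
    return math.sqrt(msd)


class TestCavityAndDistanceRestraints:
    def grid(self):
        inside = np.zeros((3, 3, 3), dtype=bool)
        inside[1, 1, 1] = True
        return CavityGrid(np.zeros(3), 1.0, inside)

    def test_all_heavy_inside_is_zero(self, ligand_from_smiles):
        grid = self.grid()
        lig = ligand_from_smiles("C", name="methane")
        c = lig.molecule.coords
        shift = np.array([1.0, 1.0, 1.0]) - c[0]
        assert cavity_penalty(lig.with_coords(c + shift), grid) == 0.0

    def test_one_atom_two_angstrom_outside(self):
        from gadock.restraints import cavity_penalty_coords

        grid = self.grid()
        pen = cavity_penalty_coords(np.array([[1.0, 1.0, 3.0]]), grid, 1.0)
        assert pen == pytest.approx(4.0)

    def test_hydrogens_do_not_count(self, ligand_from_smiles):
        grid = self.grid()
        lig = ligand_from_smiles("C", name="methane")
        c = lig.molecule.coords.copy()
        shift = np.array([1.0, 1.0, 1.0]) - c[0]
        c = c + shift
        # push hydrogens far outside; the heavy atom stays at the grid point
        for i, e in enumerate(lig.molecule.elements):
            if e == "H":
                c[i] = [50.0, 50.0, 50.0]
        assert cavity_penalty(lig.with_coords(c), grid) == 0.0

    def test_nmr_upper_bound_semantics(self):
        rec = Receptor(simple_molecule(["O"], [[0.0, 0, 0]], []))
        dr = DistanceRestraint([0], [0], bound=3.0, weight=1.0)
        near = np.array([[2.0, 0, 0]])
        far = np.array([[4.0, 0, 0]])
        assert nmr_distance_penalty(near, rec, dr) == 0.0
        assert nmr_distance_penalty(far, rec, dr) == pytest.approx(1.0)

    def test_minimum_pair_distance_counts(self):
        rec = Receptor(simple_molecule(["O"], [[0.0, 0, 0]], []))
        dr = DistanceRestraint([0, 1], [0], bound=3.0)
        coords = np.array([[10.0, 0, 0], [2.0, 0, 0]])
        assert nmr_distance_penalty(coords, rec, dr) == 0.0

    def test_lower_bound_switch(self):
        rec = Receptor(simple_molecule(["O"], [[0.0, 0, 0]], []))
        dr = DistanceRestraint([0], [0], bound=3.0, lower_bound=True)
        assert nmr_distance_penalty(np.array([[2.0, 0, 0]]), rec, dr) == pytest.approx(1.0)
        assert nmr_distance_penalty(np.array([[4.0, 0, 0]]), rec, dr) == 0.0

    def test_empty_selector_is_config_error(self):
        rec = Receptor(simple_molecule(["O"], [[0.0, 0, 0]], []))
        with pytest.raises(ValueError):
            nmr_distance_penalty(np.zeros((1, 3)), rec,
                                 DistanceRestraint([], [0], bound=3.0))
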