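"""Rigid alignment, hypothesis matching, library ranking and diversity
selection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gpr139pharm import (
    ConformerPolicy,
    align_points,
    diversity_select,
    generate_conformers,
    match,
    screen_library,
)
from gpr139pharm.chem import Molecule, mol_from_smiles
from gpr139pharm.hypothesis import ExclusionSphere, Hypothesis, gpr139_model
from gpr139pharm.screen import MatchResult, ScreenReport


def brute_force_rmsd(ref, mov, seeds=8):
    """Independent oracle: minimize RMSD over rotations parameterized by
    rotation vectors, multi-start coarse grid + local refinement."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)

    def cost(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mov_c @ rot.T - ref_c) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(0)
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=rng).as_rotvec() for _ in range(seeds)
    ]
    for start in starts:
        res = minimize(cost, start, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
        best = min(best, res.fun)
    return best


class TestAlignPoints:
    def test_identical_sets_give_zero_rmsd_identity_transform(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        rot, trans, rmsd = align_points(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_exact_rigid_motion_recovered(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot90.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = align_points(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved @ rot.T + trans, pts, atol=1e-9)

    def test_perturbed_points_match_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3))
        noisy = pts @ Rotation.random(random_state=rng).as_matrix().T + rng.normal(
            scale=0.1, size=(4, 3)
        )
        _rot, _t, rmsd = align_points(pts, noisy)
        assert rmsd == pytest.approx(brute_force_rmsd(pts, noisy), abs=1e-3)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a, b = rng.normal(size=(2, 5, 3))
            rot, _t, _r = align_points(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_sets_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            align_points(line, line)

    def test_fewer_than_three_points_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(ValueError):
            align_points(pts, pts)


class TestMatch:
    def test_1a_self_match_is_perfect(self, ensemble_1a, model):
        result = match(ensemble_1a, model)
        assert result.matched_count == 7
        assert result.rmsd < 0.01
        assert result.fitness == pytest.approx(2.0, abs=1e-3)
        assert not result.excluded

    def test_dl96_topology_never_reaches_seven_sites(self, ensemble_dl96, model):
        result = match(ensemble_dl96, model)
        assert result.matched_count < 7 or result.excluded

    def test_under_featured_molecule_scores_zero(self, model):
        benzene = generate_conformers(
            mol_from_smiles("c1ccccc1", "benzene"), ConformerPolicy(seed=1)
        )
        result = match(benzene, model)
        assert result.matched_count == 0
        assert result.fitness == 0.0

    def test_fitness_in_range_and_consistent(self, ensemble_1a, ensemble_dl96, model):
        for mol in (ensemble_1a, ensemble_dl96):
            r = match(mol, model)
            assert 0.0 <= r.fitness <= 2.0
            if r.matched_count >= model.min_match and not r.excluded:
                expected = r.matched_count / 7 + max(0.0, 1.0 - r.rmsd / 2.0)
                assert r.fitness == pytest.approx(expected, abs=1e-9)
                assert len(r.correspondence) == r.matched_count

    def test_match_invariant_under_rigid_motion(self, ensemble_1a, model):
        r_ref = match(ensemble_1a, model)
        rng = np.random.default_rng(11)
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.normal(size=3) * 10
        from rdkit import Chem

        moved = Chem.Mol(ensemble_1a.mol)
        for conf in moved.GetConformers():
            pos = conf.GetPositions() @ rot.T + shift
            for i, xyz in enumerate(pos):
                conf.SetAtomPosition(i, xyz.tolist())
        r_moved = match(Molecule("1a", moved, list(ensemble_1a.energies)), model)
        assert r_moved.matched_count == r_ref.matched_count
        assert r_moved.fitness == pytest.approx(r_ref.fitness, abs=1e-6)

    def test_match_quality_monotone_in_site_tolerance(self, ensemble_1a, ensemble_dl96):
        # Tightening the tolerance can only shrink the set of admissible
        # correspondences: the matched count is non-increasing, and at a
        # fixed matched count the RMSD is non-decreasing.  (Raw fitness can
        # legitimately rise when a dropped site leaves a much tighter
        # partial fit, so the monotone quantity is the (count, -rmsd) pair.)
        for mol in (ensemble_1a, ensemble_dl96):
            results = [
                match(mol, gpr139_model(tolerance=tol)) for tol in (1.5, 1.0, 0.5)
            ]
            counts = [r.matched_count for r in results]
            assert counts == sorted(counts, reverse=True)
            for a, b in zip(results, results[1:]):
                if a.matched_count == b.matched_count:
                    assert b.rmsd >= a.rmsd - 1e-12
                    assert b.fitness <= a.fitness + 1e-12

    def test_adding_exclusion_sphere_never_increases_fitness(self, ensemble_1a, ensemble_dl96, model):
        for mol in (ensemble_1a, ensemble_dl96):
            before = match(mol, model)
            bigger = Hypothesis(
                sites=list(model.sites),
                exclusions=list(model.exclusions)
                + [ExclusionSphere(model.site("R2").position + [0.0, 0.0, 2.0], 1.2, "extra")],
                min_match=model.min_match,
                provenance=model.provenance,
            )
            after = match(mol, bigger)
            assert after.fitness <= before.fitness + 1e-12

    def test_no_conformers_is_an_error(self, model):
        with pytest.raises(ValueError):
            match(mol_from_smiles("CCO", "ethanol"), model)


class TestScreenLibrary:
    def test_single_molecule_report(self, ensemble_1a, model):
        report = screen_library([ensemble_1a], model)
        assert len(report.results) == 1
        assert report.results[0].fitness == pytest.approx(2.0, abs=1e-3)

    def test_report_ranking_is_deterministic_and_sorted(self, ensemble_1a, ensemble_dl96, model, tmp_path):
        lib = [ensemble_dl96, ensemble_1a]
        r1 = screen_library(lib, model)
        r2 = screen_library(lib, model)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        r1.to_csv(p1)
        r2.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        fits = [r.fitness for r in r1.results]
        assert fits == sorted(fits, reverse=True)

    def test_empty_library_rejected(self, model):
        with pytest.raises(ValueError):
            screen_library([], model)

    def test_actives_outrank_decoy_candidates(self, model):
        from gpr139pharm.synth import generate_actives, generate_decoy_candidates

        actives = generate_actives(10, 11)
        decoys = generate_decoy_candidates(10, 11, actives)
        policy = ConformerPolicy(max_conformers=6, minimize_iterations=60, seed=11)
        report = screen_library(actives + decoys, model, policy)
        from gpr139pharm.validate import roc

        active_ids = {m.id for m in actives}
        scored = [
            (r.fitness, "active" if r.molecule_id in active_ids else "decoy")
            for r in report.results
        ]
        # strong (not necessarily total) separation of actives from decoys
        assert roc(scored).auc >= 0.9


class TestDiversitySelect:
    def _report(self, ids):
        results = [
            MatchResult(molecule_id=i, matched_count=7, rmsd=0.1, fitness=2.0 - k * 0.01)
            for k, i in enumerate(ids)
        ]
        return ScreenReport(results)

    def test_identical_copies_collapse_to_one_leader(self):
        mols = [mol_from_smiles("c1ccccc1CCO", f"m{i}") for i in range(4)]
        report = self._report([m.id for m in mols])
        with pytest.warns(UserWarning, match="clusters"):
            leaders = diversity_select(report, mols, n=5)
        assert len(leaders) == 1

    def test_dissimilar_molecules_all_kept_in_fitness_order(self):
        mols = [
            mol_from_smiles("CCCCCCCC", "alkane"),
            mol_from_smiles("c1ccc2ccccc2c1", "naphthalene"),
            mol_from_smiles("OC(=O)CC(O)C(N)=O", "polar"),
        ]
        leaders = diversity_select(self._report([m.id for m in mols]), mols, n=3)
        assert leaders == ["alkane", "naphthalene", "polar"]

    def test_selection_count_monotone_in_cutoff(self):
        from gpr139pharm.synth import generate_actives

        mols = generate_actives(30, 5)
        report = self._report([m.id for m in mols])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loose = diversity_select(report, mols, n=30, similarity_cutoff=0.9)
            tight = diversity_select(report, mols, n=30, similarity_cutoff=0.6)
        assert len(loose) >= len(tight)
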