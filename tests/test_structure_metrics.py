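"""Superposition, symmetry-aware region RMSDs, diversity and improvement."""

import math

import numpy as np
import pytest

from screeneval.structure import (
    EmptyRegionError,
    InsufficientOverlapError,
    RegionDefinition,
    StructureParseError,
    improvement_fraction,
    pairwise_diversity,
    read_structure,
    region_rmsd,
    rmsd_report,
    superpose,
    write_structure,
)
from screeneval.synthetic import gen_perturbed_structure, gen_toy_structure, toy_regions


class TestPdbIO:
    def test_toy_fixture_parses(self):
        text = (
            "ATOM      1  N   ALA A   1      -1.200   0.600   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       1.100   0.800   0.300  1.00  0.00           C\n"
            "ATOM      4  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ATOM      5  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        model = read_structure(text)
        assert len(model.residue_keys) == 3
        assert len(model) == 5

    def test_altloc_resolves_to_highest_occupancy(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        model = read_structure(text)
        assert len(model) == 1
        assert model.atoms[0].position[0] == pytest.approx(9.0)

    def test_waters_and_hydrogens_excluded(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       0.500   0.500   0.000  1.00  0.00           H\n"
            "HETATM    3  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O\n"
            "END\n"
        )
        assert len(read_structure(text)) == 1

    def test_no_atoms_is_parse_error(self):
        with pytest.raises(StructureParseError):
            read_structure("REMARK nothing here\nEND\n")

    def test_malformed_coordinate_reports_line(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       xx.xxx   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(StructureParseError, match="line 2"):
            read_structure(text)

    def test_round_trip_preserves_coordinates(self, toy_structure):
        back = read_structure(write_structure(toy_structure))
        assert len(back) == len(toy_structure)
        for a, b in zip(toy_structure.atoms, back.atoms):
            assert (a.chain, a.residue_number, a.residue_name, a.atom_name) == (
                b.chain,
                b.residue_number,
                b.residue_name,
                b.atom_name,
            )
            assert np.allclose(a.position, b.position, atol=1e-3)


class TestSuperpose:
    def test_identity_on_self(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        t = superpose(toy_structure, toy_structure, tm)
        assert t.fit_rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)

    def test_recovers_pure_translation(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        moved = toy_structure.with_coords(toy_structure.coords() + [5.0, 0.0, 0.0])
        t = superpose(moved, toy_structure, tm)
        assert t.fit_rmsd == pytest.approx(0.0, abs=1e-9)
        fitted = t.apply_to(moved)
        assert np.allclose(fitted.coords(), toy_structure.coords(), atol=1e-9)

    def test_noisy_fit_rmsd_near_sqrt3_sigma(self):
        # ~50 residues -> 200 backbone atoms; fit RMSD concentrates on sqrt(3)*sigma
        base = gen_toy_structure(50)
        tm, _ = toy_regions(50)
        sigma = 0.3
        pert = gen_perturbed_structure(base, sigma, seed=4)
        rng = np.random.default_rng(8)
        # arbitrary rigid motion on top of the noise
        angle = 1.1
        rot = np.array(
            [
                [math.cos(angle), -math.sin(angle), 0],
                [math.sin(angle), math.cos(angle), 0],
                [0, 0, 1],
            ]
        )
        moved = pert.with_coords(pert.coords() @ rot + rng.normal(0, 10, 3))
        t = superpose(moved, base, tm)
        assert t.fit_rmsd == pytest.approx(math.sqrt(3) * sigma, rel=0.2)

    def test_insufficient_overlap(self, toy_structure):
        region = RegionDefinition("tiny", frozenset({("Z", 999)}))
        with pytest.raises(InsufficientOverlapError):
            superpose(toy_structure, toy_structure, region)


class TestRegionRmsd:
    def test_self_comparison_is_zero(self, toy_structure, toy_region_pair):
        tm, bs = toy_region_pair
        for region in (tm, bs):
            for cls in ("backbone", "sidechain_heavy"):
                value, n = region_rmsd(toy_structure, toy_structure, region, cls, True)
                assert value == pytest.approx(0.0, abs=1e-12)
                assert n > 0

    def test_uniform_displacement(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        moved = toy_structure.with_coords(toy_structure.coords() + [1.0, 0.0, 0.0])
        value, _ = region_rmsd(moved, toy_structure, tm, "backbone")
        assert value == pytest.approx(1.0, abs=1e-12)

    def test_ring_flip_forgiven_only_with_symmetry(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        flipped = gen_perturbed_structure(
            toy_structure, 0.0, relabel_symmetric=True, seed=3, relabel_probability=1.0
        )
        naive, _ = region_rmsd(flipped, toy_structure, tm, "sidechain_heavy", False)
        sym, _ = region_rmsd(flipped, toy_structure, tm, "sidechain_heavy", True)
        assert naive > 0.5
        assert sym == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_never_increases_rmsd(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        for seed in range(5):
            pert = gen_perturbed_structure(
                toy_structure, 0.4, relabel_symmetric=True, seed=seed
            )
            naive, _ = region_rmsd(pert, toy_structure, tm, "sidechain_heavy", False)
            sym, _ = region_rmsd(pert, toy_structure, tm, "sidechain_heavy", True)
            assert sym <= naive + 1e-12

    def test_metric_symmetry(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        pert = gen_perturbed_structure(toy_structure, 0.5, seed=9)
        ab, _ = region_rmsd(pert, toy_structure, tm, "sidechain_heavy", True)
        ba, _ = region_rmsd(toy_structure, pert, tm, "sidechain_heavy", True)
        assert ab == pytest.approx(ba)

    def test_rigid_motion_of_both_is_invariant(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        pert = gen_perturbed_structure(toy_structure, 0.5, seed=12)
        before, _ = region_rmsd(pert, toy_structure, tm, "backbone")
        angle = 0.7
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(angle), -math.sin(angle)],
                [0, math.sin(angle), math.cos(angle)],
            ]
        )
        shift = np.array([3.0, -2.0, 8.0])
        a = pert.with_coords(pert.coords() @ rot + shift)
        b = toy_structure.with_coords(toy_structure.coords() @ rot + shift)
        after, _ = region_rmsd(a, b, tm, "backbone")
        assert after == pytest.approx(before, abs=1e-9)

    def test_empty_region_raises(self, toy_structure):
        region = RegionDefinition("gone", frozenset({("B", 1)}))
        with pytest.raises(EmptyRegionError):
            region_rmsd(toy_structure, toy_structure, region)

    def test_report_invariants(self, toy_structure, toy_region_pair):
        tm, bs = toy_region_pair
        pert = gen_perturbed_structure(toy_structure, 0.5, seed=2)
        rep = rmsd_report(pert, toy_structure, tm, bs)
        assert rep.rmsd_tmbb >= 0 and rep.rmsd_bsbb >= 0 and rep.rmsd_bssc >= 0
        assert rep.symmetry_corrected
        assert rep.n_bsbb <= rep.n_tmbb


class TestPairwiseDiversity:
    def test_duplicates_give_zero_matrix(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        matrix, mean = pairwise_diversity(
            [toy_structure, toy_structure, toy_structure], tm, "sidechain_heavy", tm
        )
        assert np.allclose(matrix, 0.0, atol=1e-9)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_matrix_matches_per_pair_recomputation(self, toy_region_pair):
        tm, _ = toy_region_pair
        base = gen_toy_structure(30)
        models = [
            gen_perturbed_structure(base, 0.4, seed=s, model_id=f"m{s}") for s in range(3)
        ]
        matrix, _ = pairwise_diversity(models, tm, "sidechain_heavy", tm)
        assert np.allclose(matrix, matrix.T)
        assert np.allclose(np.diag(matrix), 0.0)
        for i in range(3):
            for j in range(i + 1, 3):
                fitted = superpose(models[i], models[j], tm).apply_to(models[i])
                value, _ = region_rmsd(fitted, models[j], tm, "sidechain_heavy", True)
                assert matrix[i, j] == pytest.approx(value)

    def test_independent_noise_expectation(self):
        # two models perturbed by sigma each differ by sqrt(2)*sigma per axis
        base = gen_toy_structure(80)
        tm, _ = toy_regions(80)
        sigma = 0.5
        models = [
            gen_perturbed_structure(base, sigma, seed=s, model_id=f"m{s}")
            for s in range(4)
        ]
        _, mean = pairwise_diversity(models, tm, "sidechain_heavy", tm)
        assert mean == pytest.approx(math.sqrt(2) * math.sqrt(3) * sigma, rel=0.2)


class TestImprovementFraction:
    def test_copies_of_baseline_never_improve(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        baseline = gen_perturbed_structure(toy_structure, 0.5, seed=1)
        frac = improvement_fraction(
            [baseline, baseline], toy_structure, baseline, tm, "backbone", tm
        )
        assert frac == 0.0

    def test_copies_of_reference_always_improve(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        baseline = gen_perturbed_structure(toy_structure, 0.5, seed=1)
        frac = improvement_fraction(
            [toy_structure, toy_structure], toy_structure, baseline, tm, "backbone", tm
        )
        assert frac == 1.0

    def test_mixed_set_matches_hand_count(self, toy_structure, toy_region_pair):
        tm, _ = toy_region_pair
        baseline = gen_perturbed_structure(toy_structure, 0.5, seed=10)
        candidates = [
            gen_perturbed_structure(toy_structure, s, seed=50 + i, model_id=f"c{i}")
            for i, s in enumerate([0.1, 0.1, 0.1, 1.5, 1.5])
        ]

        def rmsd_to_ref(m):
            fitted = superpose(m, toy_structure, tm).apply_to(m)
            return region_rmsd(fitted, toy_structure, tm, "backbone", True)[0]

        base_val = rmsd_to_ref(baseline)
        expected = sum(rmsd_to_ref(c) < base_val for c in candidates) / 5
        got = improvement_fraction(
            candidates, toy_structure, baseline, tm, "backbone", tm
        )
        assert got == pytest.approx(expected)
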