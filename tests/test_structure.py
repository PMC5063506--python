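"""PDB I/O, Kabsch superposition, distance rules and residue context."""

import numpy as np
import pytest

from specmap.errors import InputError, ParseError
from specmap.structure import (INTERFACE, POCKET, SURFACE_DISTAL,
                               build_chimeric_receptor,
                               classify_residue_context, conformational_rmsd,
                               kabsch_superpose, min_distance, parse_selection,
                               read_structure, residue_min_distance,
                               superpose_by_selection, write_structure)
from specmap import synth

from conftest import make_structure, random_rotation


# ---------------------------------------------------------------------------
# PDB round trip
# ---------------------------------------------------------------------------

class TestPdbIO:
    def test_synthetic_complex_roundtrips_to_pdb_precision(self, toy_complex):
        bound, _ = toy_complex
        text = write_structure(bound)
        back = read_structure(text, roles=bound.roles, ligand=bound.ligand)
        for (c1, r1), (c2, r2) in zip(bound.iter_residues(), back.iter_residues()):
            assert (c1.id, r1.key, r1.name) == (c2.id, r2.key, r2.name)
            np.testing.assert_allclose(r1.coords(), r2.coords(), atol=5e-4)

    def test_second_roundtrip_is_idempotent(self, toy_complex):
        bound, _ = toy_complex
        text = write_structure(read_structure(write_structure(bound)))
        assert text == write_structure(read_structure(text))

    def test_duplicate_atom_key_is_an_error_with_line_number(self):
        line = "ATOM      1  CA  ALA C   1       0.000   0.000   0.000  1.00  0.00           C"
        with pytest.raises(ParseError, match="line 2.*duplicate"):
            read_structure(line + "\n" + line)

    def test_malformed_coordinates_report_the_line(self):
        bad = "ATOM      1  CA  ALA C   1       xx.000   0.000   0.000  1.00  0.00           C"
        with pytest.raises(ParseError, match="line 1"):
            read_structure(bad)

    def test_altloc_keeps_highest_occupancy_conformer(self):
        text = (
            "ATOM      1  CA AALA C   1       1.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA C   1       2.000   0.000   0.000  0.60  0.00           C\n"
        )
        model = read_structure(text)
        assert model.chain("C").residue(1).atoms[0].coord[0] == 2.0

    def test_multichain_order_matches_independent_parser(self, toy_complex):
        gemmi = pytest.importorskip("gemmi")
        bound, _ = toy_complex
        text = write_structure(bound)
        ours = read_structure(text)
        theirs = gemmi.read_pdb_string(text)
        g_chains = [c.name for c in theirs[0]]
        assert [c.id for c in ours.chains] == g_chains
        g_atoms = [(cra.chain.name, cra.residue.seqid.num, cra.atom.name,
                    round(cra.atom.pos.x, 3))
                   for cra in theirs[0].all()]
        o_atoms = [(c.id, r.seqnum, a.name, round(float(a.coord[0]), 3))
                   for c, r in ours.iter_residues() for a in r.atoms]
        assert o_atoms == g_atoms

    def test_empty_text_rejected(self):
        with pytest.raises(ParseError):
            read_structure("HEADER nothing\nEND\n")


def test_selection_parser_ranges_and_errors():
    assert parse_selection("C:5-7,A:3") == {("C", 5), ("C", 6), ("C", 7), ("A", 3)}
    with pytest.raises(InputError):
        parse_selection("C5")
    with pytest.raises(InputError):
        parse_selection("")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_identical_point_sets(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        sup = kabsch_superpose(P, P)
        assert sup.rmsd < 1e-12
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_an_applied_rigid_transform(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(7, 3))
        theta = np.deg2rad(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        t = np.array([1.0, -2.0, 3.0])
        Q = P @ R.T + t
        sup = kabsch_superpose(P, Q)
        assert sup.rmsd < 1e-9
        np.testing.assert_allclose(sup.rotation, R, atol=1e-9)
        np.testing.assert_allclose(sup.translation, t, atol=1e-9)

    def test_rmsd_is_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert kabsch_superpose(A, B).rmsd == pytest.approx(
            kabsch_superpose(B, A).rmsd, abs=1e-9)

    def test_rotation_is_proper_and_orthonormal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A, B = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
            R = kabsch_superpose(A, B).rotation
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-8)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_scipy_rotation_fit(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(3)
        for _ in range(10):
            A, B = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
            sup = kabsch_superpose(A, B)
            rot, _ = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
            np.testing.assert_allclose(sup.rotation, rot.as_matrix(), atol=1e-6)

    def test_matches_grid_search_oracle_on_five_points(self):
        """Kabsch RMSD must lower-bound (within grid resolution) a brute
        search over proper rotations with centroid-matching translation."""
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(4)
        step = 12.0
        angles = np.arange(0.0, 360.0, step)
        half = np.arange(-90.0, 90.1, step)
        grid = [Rotation.from_euler("zyz", [a, b, c], degrees=True).as_matrix()
                for a in angles for b in half for c in angles]
        for _ in range(3):
            A, B = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
            sup = kabsch_superpose(A, B)
            A0, B0 = A - A.mean(0), B - B.mean(0)
            grid_best = min(
                np.sqrt(((A0 @ R.T - B0) ** 2).sum() / 5) for R in grid)
            assert sup.rmsd <= grid_best + 1e-9
            assert grid_best - sup.rmsd < 0.5  # coarse-grid slack

    def test_mismatched_counts_rejected(self):
        with pytest.raises(InputError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_points_warn_but_return(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.warns(UserWarning, match="degenerate"):
            sup = kabsch_superpose(P, P + np.array([1.0, 2.0, 3.0]))
        assert sup.rmsd < 1e-9


class TestSuperposeBySelection:
    def test_nonloop_selection_superposes_exactly(self, toy_complex, structure_truth):
        bound, unbound = toy_complex
        sel = {("C", r.seqnum) for r in bound.chain("C").residues
               if r.seqnum not in structure_truth.loop_ids}
        _, sup = superpose_by_selection(unbound, bound, selection=sel)
        assert sup.rmsd < 1e-6

    def test_loop_displacement_recovered_after_nonloop_fit(self, toy_complex,
                                                           structure_truth):
        bound, unbound = toy_complex
        sel = {("C", r.seqnum) for r in bound.chain("C").residues
               if r.seqnum not in structure_truth.loop_ids}
        moved, _ = superpose_by_selection(unbound, bound, selection=sel)
        planted = np.linalg.norm(structure_truth.loop_displacement)
        for i in structure_truth.loop_ids:
            d = np.linalg.norm(moved.chain("C").residue(i).atoms[0].coord
                               - bound.chain("C").residue(i).atoms[0].coord)
            assert d == pytest.approx(planted, abs=1e-6)

    def test_disjoint_numbering_rejected(self, toy_complex):
        bound, unbound = toy_complex
        with pytest.raises(InputError, match="matched atoms"):
            superpose_by_selection(unbound, bound, selection={("C", 9999)})


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_three_four_five_triangle(self):
        s = make_structure([(0.0, 0.0, 0.0)], ligand_positions=[(3.0, 4.0, 0.0)])
        assert residue_min_distance(s, "C", 1, s.ligand_coords()) == pytest.approx(5.0)

    def test_coincident_atoms_give_zero(self):
        s = make_structure([(1.0, 1.0, 1.0)], ligand_positions=[(1.0, 1.0, 1.0)])
        assert residue_min_distance(s, "C", 1, s.ligand_coords()) == 0.0

    def test_kdtree_path_equals_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            A = rng.uniform(-20, 20, size=(rng.integers(1, 30), 3))
            B = rng.uniform(-20, 20, size=(rng.integers(1, 30), 3))
            assert min_distance(A, B, method="kdtree") == pytest.approx(
                min_distance(A, B, method="brute"), abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(InputError):
            min_distance(np.empty((0, 3)), np.zeros((1, 3)))


# ---------------------------------------------------------------------------
# residue context
# ---------------------------------------------------------------------------

class TestResidueContext:
    def test_planted_classes_recovered(self, toy_complex, structure_truth):
        bound, _ = toy_complex
        t = structure_truth
        residues = [("C", i) for i in t.pocket_ids + t.interface_ids + t.surface_ids]
        ctx = {c.seqnum: c.context for c in classify_residue_context(bound, residues)}
        for i in t.pocket_ids:
            assert ctx[i] == POCKET
        for i in t.interface_ids:
            assert ctx[i] == INTERFACE
        for i in t.surface_ids:
            assert ctx[i] == SURFACE_DISTAL

    def test_interface_edge_residue_between_cutoffs(self):
        # 3.9 A from the partner, far from the ligand -> interface class
        s = make_structure([(0.0, 3.9, 0.0)], ligand_positions=[(30.0, 0.0, 0.0)],
                           partner_positions=[(0.0, 0.0, 0.0)])
        (c,) = classify_residue_context(s, [("C", 1)])
        assert c.context == INTERFACE
        assert c.partner_distance == pytest.approx(3.9)

    def test_pocket_takes_precedence_over_interface(self):
        s = make_structure([(0.0, 0.0, 0.0)], ligand_positions=[(3.0, 0.0, 0.0)],
                           partner_positions=[(0.0, 3.0, 0.0)])
        (c,) = classify_residue_context(s, [("C", 1)])
        assert c.context == POCKET

    def test_untagged_ligand_rejected(self):
        s = make_structure([(0.0, 0.0, 0.0)])
        with pytest.raises(InputError, match="ligand"):
            classify_residue_context(s, [("C", 1)])

    def test_classification_invariant_under_joint_rigid_transform(self, toy_complex,
                                                                  structure_truth):
        bound, _ = toy_complex
        rng = np.random.default_rng(13)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = bound.transform(R, t)
        res = [("C", i) for i in structure_truth.pocket_ids
               + structure_truth.interface_ids + structure_truth.surface_ids]
        before = [(c.seqnum, c.context) for c in classify_residue_context(bound, res)]
        after = [(c.seqnum, c.context) for c in classify_residue_context(moved, res)]
        assert before == after

    def test_planted_recovery_across_many_seeds(self, structure_truth):
        t = structure_truth
        residues = [("C", i) for i in t.pocket_ids + t.interface_ids + t.surface_ids]
        expected = {**{i: POCKET for i in t.pocket_ids},
                    **{i: INTERFACE for i in t.interface_ids},
                    **{i: SURFACE_DISTAL for i in t.surface_ids}}
        for seed in range(30):
            bound, _ = synth.gen_toy_complex(truth=t, seed=seed)
            got = {c.seqnum: c.context
                   for c in classify_residue_context(bound, residues)}
            assert got == expected, f"seed {seed}"


# ---------------------------------------------------------------------------
# conformational rmsd
# ---------------------------------------------------------------------------

class TestConformationalRmsd:
    def test_identical_models_give_zero(self, toy_complex):
        bound, _ = toy_complex
        res = [("C", r.seqnum) for r in bound.chain("C").residues]
        assert conformational_rmsd(bound, bound.copy(), res) < 1e-12

    def test_planted_jitter_magnitude_recovered(self, toy_complex):
        bound, _ = toy_complex
        rng = np.random.default_rng(5)
        jittered = bound.copy()
        sigma = 0.2
        for r in jittered.chain("C").residues:
            for a in r.atoms:
                a.coord = a.coord + rng.normal(0, sigma / np.sqrt(3), 3)
        res = [("C", r.seqnum) for r in bound.chain("C").residues]
        # default fit selection = the residues themselves
        rmsd = conformational_rmsd(bound, jittered, res)
        assert rmsd == pytest.approx(sigma, rel=0.2)

    def test_missing_residues_warn_and_use_intersection(self, toy_complex):
        bound, unbound = toy_complex
        # unbound lacks chain B entirely; ask for a residue only bound has
        res = [("C", r.seqnum) for r in bound.chain("C").residues[:5]]
        trimmed = unbound.copy()
        trimmed.chain("C").residues.pop(0)
        with pytest.warns(UserWarning, match="missing"):
            rmsd = conformational_rmsd(bound, trimmed, res)
        assert np.isfinite(rmsd)


# ---------------------------------------------------------------------------
# chimeric assembly
# ---------------------------------------------------------------------------

class TestChimera:
    def _donor_acceptor(self, seed=0):
        rng = np.random.default_rng(seed)
        shared = rng.uniform(-5, 5, size=(6, 3))
        donor = make_structure([tuple(p) for p in shared])
        graft = [tuple(p) for p in rng.uniform(5, 10, size=(4, 3))]
        from specmap.structure import Atom, Chain, Residue
        donor.chains.append(Chain("A", [
            Residue("GLY", 500 + i, atoms=[Atom("CA", "C", p)])
            for i, p in enumerate(graft)]))
        donor.roles["A"] = "receptor-A"
        acceptor = make_structure([tuple(p) for p in shared])
        return donor, acceptor

    def test_graft_adds_missing_chain_keeping_acceptor_coordinates(self):
        donor, acceptor = self._donor_acceptor()
        out, prov = build_chimeric_receptor(donor, acceptor,
                                            {("C", i) for i in range(1, 7)}, ["A"])
        assert out.has_chain("A") and out.has_chain("C")
        np.testing.assert_allclose(out.chain("C").residue(1).atoms[0].coord,
                                   acceptor.chain("C").residue(1).atoms[0].coord)
        assert prov["chain_map"] == {"A": "A"}

    def test_prealigned_shared_selection_leaves_graft_unmoved(self):
        donor, acceptor = self._donor_acceptor()
        out, prov = build_chimeric_receptor(donor, acceptor,
                                            {("C", i) for i in range(1, 7)}, ["A"])
        assert prov["fit_rmsd"] < 1e-9
        for i in range(4):
            np.testing.assert_allclose(
                out.chain("A").residues[i].atoms[0].coord,
                donor.chain("A").residues[i].atoms[0].coord, atol=1e-9)

    def test_rotated_donor_is_fit_back_onto_acceptor(self):
        donor, acceptor = self._donor_acceptor(seed=1)
        R = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        rotated = donor.transform(R, np.array([3.0, -1.0, 2.0]))
        out, prov = build_chimeric_receptor(rotated, acceptor,
                                            {("C", i) for i in range(1, 7)}, ["A"])
        assert prov["fit_rmsd"] < 1e-9
        for i in range(4):
            np.testing.assert_allclose(
                out.chain("A").residues[i].atoms[0].coord,
                donor.chain("A").residues[i].atoms[0].coord, atol=1e-8)

    def test_colliding_chain_id_is_remapped(self):
        donor, acceptor = self._donor_acceptor()
        out, prov = build_chimeric_receptor(donor, acceptor,
                                            {("C", i) for i in range(1, 7)}, ["C"])
        new_id = prov["chain_map"]["C"]
        assert new_id != "C" and out.has_chain(new_id)
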