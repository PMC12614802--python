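"""Geometric primitives: radii, neighbor search, centers, H-bonds, ASA."""

import math

import numpy as np
import pytest

from interactor import (DEFAULT_CONFIG, assign_vdw_radii, compute_asa,
                        detect_hbonds, geometric_center, hbond_angle,
                        neighbor_pairs)
from interactor.geometry import golden_spiral_points

from conftest import build_structure


class TestVdwRadii:
    @pytest.mark.parametrize("element,name,expected",
                             [("C", "CB", 1.70), ("O", "OD", 1.52),
                              ("N", "ND", 1.55), ("S", "SD", 1.80)])
    def test_table_lookup(self, element, name, expected):
        s = build_structure([(name, element, [0, 0, 0], 0, "A"),
                             ("CB", "C", [9, 9, 9], 1, "A")])
        assign_vdw_radii(s)
        assert s.atoms[0].vdw_radius == expected

    def test_unknown_element_gets_default_with_warning(self, caplog):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [9, 9, 9], 1, "A")])
        s.atoms[0].element = "QQ"
        with caplog.at_level("WARNING"):
            assign_vdw_radii(s)
        assert s.atoms[0].vdw_radius == DEFAULT_CONFIG.default_vdw_radius
        assert "QQ" in caplog.text


class TestNeighborPairs:
    def test_collinear_atoms_cutoff(self):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [2, 0, 0], 1, "A"),
                             ("CB", "C", [4, 0, 0], 2, "A")])
        pairs = {(p.atom_i, p.atom_j) for p in neighbor_pairs(s, 3.0)}
        assert pairs == {(0, 1), (1, 2)}

    def test_matches_brute_force_on_random_cloud(self):
        from interactor import make_atom_cloud

        s = make_atom_cloud(50, box=12.0, seed=7)
        cutoff = 5.0
        coords = s.coords()
        expected = {(i, j)
                    for i in range(50) for j in range(i + 1, 50)
                    if np.linalg.norm(coords[i] - coords[j]) <= cutoff}
        got = {(p.atom_i, p.atom_j) for p in neighbor_pairs(s, cutoff)}
        assert got == expected

    def test_cutoff_below_min_distance_gives_empty(self):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [5, 0, 0], 1, "A")])
        assert neighbor_pairs(s, 1.0) == []

    def test_rejects_nonpositive_cutoff(self):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [5, 0, 0], 1, "A")])
        with pytest.raises(ValueError):
            neighbor_pairs(s, 0.0)


class TestGeometricCenter:
    @staticmethod
    def _with_bonds(specs, bonds):
        from interactor import BondGraph

        s = build_structure(specs)
        graph = BondGraph()
        for i, j in bonds:
            graph.add_bond(i, j)
        s.bonds = graph
        return s

    def test_single_neighbor(self):
        s = self._with_bonds([("CB", "C", [0, 0, 0], 0, "A"),
                              ("CB", "C", [2, 0, 0], 1, "A")], [(0, 1)])
        np.testing.assert_allclose(geometric_center(s, 0), [1, 0, 0])

    def test_symmetric_neighbors(self):
        s = self._with_bonds([("CB", "C", [0, 0, 0], 0, "A"),
                              ("CB", "C", [1, 0, 0], 1, "A"),
                              ("CB", "C", [-1, 0, 0], 2, "A")],
                             [(0, 1), (0, 2)])
        np.testing.assert_allclose(geometric_center(s, 0), [0, 0, 0],
                                   atol=1e-12)

    def test_carbonyl_oxygen_center_matches_hand_computation(self, helix10):
        structure, _ = helix10
        o_id = next(i for i, a in enumerate(structure.atoms)
                    if a.name == "O")
        c_id = next(i for i, a in enumerate(structure.atoms)
                    if a.name == "C")
        # O is covalently bound to C only: center = midpoint of O and C
        expected = 0.5 * (structure.atoms[o_id].coords
                          + structure.atoms[c_id].coords)
        np.testing.assert_allclose(geometric_center(structure, o_id),
                                   expected, atol=1e-12)

    def test_isolated_atom_is_an_error(self):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [9, 9, 9], 1, "A")])
        with pytest.raises(ValueError, match="no covalent neighbors"):
            geometric_center(s, 0)


def _donor_acceptor_structure(acceptor_xyz, d_da=None):
    """Donor N (neighbor C anti along -x) and a lone-ish acceptor O."""
    specs = [("N", "N", [0, 0, 0], 0, "G"),
             ("CA", "C", [-1.4, 0, 0], 0, "G"),
             ("O", "O", acceptor_xyz, 1, "G"),
             ("C", "C", np.asarray(acceptor_xyz) + [0, 1.23, 0], 1, "G")]
    return build_structure(specs)


class TestHBondGeometry:
    def test_antipodal_acceptor_gives_180(self):
        s = _donor_acceptor_structure([3.0, 0, 0])
        assert hbond_angle(s, 0, 2) == pytest.approx(180.0)

    def test_perpendicular_acceptor_gives_90(self):
        s = _donor_acceptor_structure([0, 0, 3.0])
        assert hbond_angle(s, 0, 2) == pytest.approx(90.0)

    def test_helix_i_to_i4_angle_range(self, helix10):
        structure, _ = helix10
        atom = {(a.residue_index, a.name): i
                for i, a in enumerate(structure.atoms)}
        for i in range(6):
            alpha = hbond_angle(structure, atom[(i + 4, "N")],
                                atom[(i, "O")])
            assert 140.0 <= alpha <= 180.0


class TestDetectHbonds:
    def test_ideal_pair_scores_one(self):
        s = _donor_acceptor_structure([2.6, 0, 0])
        records = detect_hbonds(s)
        assert len(records) == 1
        assert records[0].score == pytest.approx(1.0)
        assert records[0].alpha == pytest.approx(180.0)

    def test_boundary_distance_scores_zero(self):
        s = _donor_acceptor_structure([3.5, 0, 0])
        scores = [r.score for r in detect_hbonds(s)]
        assert all(score == pytest.approx(0.0) for score in scores)

    def test_beyond_cutoff_not_reported(self):
        s = _donor_acceptor_structure([3.6, 0, 0])
        assert detect_hbonds(s) == []

    @pytest.mark.parametrize("n_res", [5, 10, 20])
    def test_helix_recovers_i_to_i4_backbone_pattern(self, n_res):
        from interactor import make_ideal_helix

        structure, gt = make_ideal_helix(n_res)
        records = detect_hbonds(structure)
        found = {(structure.atoms[r.donor_atom].residue_index,
                  structure.atoms[r.acceptor_atom].residue_index)
                 for r in records
                 if structure.atoms[r.donor_atom].name == "N"
                 and structure.atoms[r.acceptor_atom].name == "O"}
        expected = set(map(tuple, gt["expected_hbond_residue_pairs"]))
        assert expected <= found
        assert len(records) >= gt["n_expected_hbonds"]

    def test_score_monotonicity_in_distance_and_angle(self):
        base = detect_hbonds(_donor_acceptor_structure([2.8, 0, 0]))[0]
        farther = detect_hbonds(_donor_acceptor_structure([3.2, 0, 0]))[0]
        assert farther.score < base.score
        bent = detect_hbonds(_donor_acceptor_structure([2.6, 1.4, 0]))[0]
        ideal = detect_hbonds(_donor_acceptor_structure([2.6, 0, 0]))[0]
        assert bent.alpha < ideal.alpha
        assert bent.score < ideal.score

    def test_hydrogens_do_not_change_output(self, helix10):
        structure, _ = helix10
        from interactor import parse_pdb, structure_to_pdb

        text = structure_to_pdb(structure)
        lines = text.splitlines()
        # graft an amide hydrogen next to every backbone N
        h_lines = []
        serial = 900
        for a in structure.atoms:
            if a.name == "N":
                x, y, z = a.coords + [0.6, 0.6, 0.4]
                serial += 1
                h_lines.append(
                    f"ATOM  {serial:5d}  H   ALA A"
                    f"{a.residue_index + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           H")
        with_h = "\n".join(lines[:-2] + h_lines + lines[-2:]) + "\n"
        s_h = parse_pdb(with_h)[0]
        rec0 = detect_hbonds(structure)
        rec1 = detect_hbonds(s_h)
        assert [(r.d_DA, r.alpha, r.score) for r in rec0] == \
               pytest.approx([(r.d_DA, r.alpha, r.score) for r in rec1])


class TestAsa:
    def test_isolated_carbon_closed_form(self):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [99, 99, 99], 1, "A")])
        assign_vdw_radii(s)
        result = compute_asa(s)
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.per_atom_asa[0] == pytest.approx(expected,
                                                       rel=0.005)

    def test_fully_overlapping_atoms_count_surface_once(self):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [0, 0, 0], 1, "A")])
        assign_vdw_radii(s)
        result = compute_asa(s)
        one_atom = 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.total_asa == pytest.approx(one_atom, rel=0.005)

    def test_two_spheres_match_monte_carlo_oracle(self):
        d = 2.0
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [d, 0, 0], 1, "A")])
        assign_vdw_radii(s)
        result = compute_asa(s, n_points=512)
        # 10^6-point Monte-Carlo oracle for one sphere of the pair
        rng = np.random.default_rng(1234)
        r = 1.70 + 1.4
        pts = rng.normal(size=(10 ** 6, 3))
        pts *= r / np.linalg.norm(pts, axis=1, keepdims=True)
        frac = np.mean(np.linalg.norm(pts - [d, 0, 0], axis=1) >= r)
        oracle = frac * 4 * math.pi * r * r
        assert result.per_atom_asa[0] == pytest.approx(oracle, rel=0.02)

    def test_point_doubling_convergence(self, helix10):
        structure, _ = helix10
        assign_vdw_radii(structure)
        a1 = compute_asa(structure, n_points=256).total_asa
        a2 = compute_asa(structure, n_points=512).total_asa
        assert abs(a2 - a1) / a1 < 0.01

    def test_accuracy_floor_enforced(self, helix10):
        structure, _ = helix10
        assign_vdw_radii(structure)
        with pytest.raises(ValueError, match="accuracy floor"):
            compute_asa(structure, n_points=16)

    def test_relative_asa_uses_gly_x_gly_reference(self):
        s = build_structure([("CB", "C", [0, 0, 0], 0, "A"),
                             ("CB", "C", [99, 99, 99], 1, "W")])
        assign_vdw_radii(s)
        result = compute_asa(s)
        one_atom = 4 * math.pi * (1.70 + 1.4) ** 2
        assert result.per_residue_relative_asa[0] == \
            pytest.approx(one_atom / 129.0, rel=0.01)
        assert result.per_residue_relative_asa[1] == \
            pytest.approx(one_atom / 285.0, rel=0.01)


class TestRigidMotionInvariance:
    def test_geometry_invariant_under_rotation_translation(self, helix10):
        from scipy.spatial.transform import Rotation

        structure, _ = helix10
        assign_vdw_radii(structure)
        ref_asa = compute_asa(structure).total_asa
        ref_hb = [(r.d_DA, r.alpha, r.score)
                  for r in detect_hbonds(structure)]

        rot = Rotation.from_euler("xyz", [31.0, -47.0, 112.0],
                                  degrees=True).as_matrix()
        shift = np.array([11.0, -3.0, 42.0])
        import copy

        moved = copy.deepcopy(structure)
        for atom in moved.atoms:
            atom.coords = rot @ atom.coords + shift
        moved._coords = None
        moved.bonds = None
        assign_vdw_radii(moved)
        assert compute_asa(moved).total_asa == pytest.approx(ref_asa,
                                                             rel=1e-6)
        moved_hb = [(r.d_DA, r.alpha, r.score)
                    for r in detect_hbonds(moved)]
        np.testing.assert_allclose(np.array(moved_hb), np.array(ref_hb),
                                   rtol=1e-6, atol=1e-9)


def test_asa_cross_checks_against_independent_implementation(helix10):
    """Total helix ASA agrees with biotite's Shrake-Rupley rolling the
    same probe over per-element radii."""
    import biotite.structure as struc

    structure, _ = helix10
    assign_vdw_radii(structure)
    mine = compute_asa(structure, n_points=512).total_asa
    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = structure.coords().astype(np.float32)
    arr.chain_id = np.array(["A"] * structure.n_atoms)
    arr.res_id = np.array([a.residue_index + 1 for a in structure.atoms])
    arr.res_name = np.array(["ALA"] * structure.n_atoms)
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    ref = struc.sasa(arr, probe_radius=1.4, point_number=512,
                     vdw_radii="Single").sum()
    assert mine == pytest.approx(float(ref), rel=0.02)


def test_golden_spiral_is_deterministic_and_unit():
    p1 = golden_spiral_points(256)
    p2 = golden_spiral_points(256)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_allclose(np.linalg.norm(p1, axis=1), 1.0, atol=1e-12)
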