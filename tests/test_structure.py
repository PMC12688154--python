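"""Structure parsing and geometric primitives."""

import math

import numpy as np
import pytest

import ddgkit as dk
from ddgkit.dataset import MutationKey
from ddgkit.structure import (
    Atom,
    PDBParseError,
    ProteinStructure,
    Residue,
    WildTypeMismatchError,
    backbone_dihedrals,
    build_mutant_baseline,
    classify_phi_psi,
    gnm_fluctuations,
    gnm_kirchhoff,
    read_pdb,
    relative_accessibility,
    residues_within_radius,
    shrake_rupley_sasa,
    write_pdb,
    MAX_ASA,
)
from ddgkit.synthetic import make_helix_structure


def _res(name3, chain, num, atoms):
    return Residue(name3=name3, chain_id=chain, author_number=num, atoms=atoms)


def _atom(name, element, x, y, z):
    return Atom(name, element, np.array([x, y, z], dtype=float))


class TestReadPDB:
    def test_roundtrip_of_helix_fixture(self):
        text = make_helix_structure("MKTAYI")
        st = read_pdb(text)
        assert st.sequence("A") == "MKTAYI"
        assert len(st) == 6

    def test_two_residue_fixture(self):
        text = make_helix_structure("AKLA")
        assert len(read_pdb(text)) == 4

    def test_altloc_highest_occupancy_kept(self):
        lines = [
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60 10.00           N",
            "ATOM      2  N  BALA A   1       1.000   0.000   0.000  0.40 10.00           N",
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C",
            "END",
        ]
        st = read_pdb("\n".join(lines))
        n = st.residues[0].atom("N")
        assert n.coords[0] == pytest.approx(0.0)  # the 0.60-occupancy conformer

    def test_hetatm_only_input_rejected(self):
        lines = [
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00 10.00           O",
            "END",
        ]
        with pytest.raises(PDBParseError):
            read_pdb("\n".join(lines))

    def test_waters_and_hetatms_excluded(self):
        text = make_helix_structure("AKLA") + (
            "HETATM  999  O   HOH A  90      50.000  50.000  50.000  1.00 10.00           O\n"
        )
        assert len(read_pdb(text)) == 4

    def test_write_parse_roundtrip_preserves_coordinates(self):
        st = read_pdb(make_helix_structure("AKLAY"))
        st2 = read_pdb(write_pdb(st))
        for r1, r2 in zip(st.residues, st2.residues):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.coords, a2.coords, atol=1e-3)


class TestMutantBaseline:
    def test_to_glycine_removes_cb(self, helix_structure):
        key = MutationKey("S000", "A", 5, "Y", "G")
        mut = build_mutant_baseline(helix_structure, key)
        res = mut.get_residue("A", 5)
        assert res.name3 == "GLY"
        assert res.atom("CB") is None
        assert mut.sidechain_incomplete

    def test_keeps_backbone_and_cb(self, helix_structure):
        key = MutationKey("S000", "A", 6, "I", "A")
        mut = build_mutant_baseline(helix_structure, key)
        names = {a.name for a in mut.get_residue("A", 6).atoms}
        assert names == {"N", "CA", "C", "O", "CB"}

    def test_wild_type_mismatch_raises(self, helix_structure):
        with pytest.raises(WildTypeMismatchError):
            build_mutant_baseline(helix_structure, MutationKey("S000", "A", 6, "K", "Q"))

    def test_missing_residue_raises(self, helix_structure):
        with pytest.raises(KeyError):
            build_mutant_baseline(helix_structure, MutationKey("S000", "A", 99, "K", "Q"))

    def test_other_residues_bit_exact(self, helix_structure):
        mut = build_mutant_baseline(helix_structure, MutationKey("S000", "A", 6, "I", "A"))
        for wt_res, mut_res in zip(helix_structure.residues, mut.residues):
            if wt_res.author_number == 6:
                continue
            for a1, a2 in zip(wt_res.atoms, mut_res.atoms):
                assert a1.name == a2.name
                assert np.array_equal(a1.coords, a2.coords)


class TestShells:
    def test_toy_distances_brute_force(self):
        # site at origin; B nearest atom at 5 A; C nearest atom at 12 A
        st = ProteinStructure(
            [
                _res("ALA", "A", 1, [_atom("CA", "C", 0, 0, 0)]),
                _res("ALA", "A", 2, [_atom("CA", "C", 5, 0, 0)]),
                _res("ALA", "A", 3, [_atom("CA", "C", 12, 0, 0)]),
            ]
        )
        s7 = residues_within_radius(st, ("A", 1, ""), 7.0)
        s13 = residues_within_radius(st, ("A", 1, ""), 13.0)
        assert s7.members == {("A", 1, ""), ("A", 2, "")}
        assert s13.members == {("A", 1, ""), ("A", 2, ""), ("A", 3, "")}

    def test_infinite_radius_returns_all(self, helix_structure):
        shell = residues_within_radius(helix_structure, ("A", 5, ""), math.inf)
        assert len(shell.members) == len(helix_structure)

    def test_nesting_over_random_sites(self, helix_structure):
        for res in helix_structure.residues:
            m7 = residues_within_radius(helix_structure, res.rid, 7.0).members
            m10 = residues_within_radius(helix_structure, res.rid, 10.0).members
            m13 = residues_within_radius(helix_structure, res.rid, 13.0).members
            assert res.rid in m7
            assert m7 <= m10 <= m13


class TestSASA:
    def test_single_atom_analytic_area(self):
        st = ProteinStructure([_res("ALA", "A", 1, [_atom("CA", "C", 0, 0, 0)])])
        area = shrake_rupley_sasa(st)[("A", 1, "")]
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_distant_atoms_do_not_occlude(self):
        st = ProteinStructure(
            [
                _res("ALA", "A", 1, [_atom("CA", "C", 0, 0, 0)]),
                _res("ALA", "A", 2, [_atom("CA", "C", 100, 0, 0)]),
            ]
        )
        sasa = shrake_rupley_sasa(st)
        single = 4 * math.pi * (1.7 + 1.4) ** 2
        assert sasa[("A", 1, "")] == pytest.approx(single, rel=0.01)
        assert sasa[("A", 2, "")] == pytest.approx(single, rel=0.01)

    def test_caged_atom_fully_occluded(self):
        # surround a central atom by a tight octahedral cage
        cage = [
            _atom(f"C{i}", "C", *pos)
            for i, pos in enumerate(
                [(2.2, 0, 0), (-2.2, 0, 0), (0, 2.2, 0), (0, -2.2, 0),
                 (0, 0, 2.2), (0, 0, -2.2),
                 (1.6, 1.6, 0), (-1.6, 1.6, 0), (1.6, -1.6, 0), (-1.6, -1.6, 0),
                 (1.6, 0, 1.6), (-1.6, 0, 1.6), (1.6, 0, -1.6), (-1.6, 0, -1.6),
                 (0, 1.6, 1.6), (0, -1.6, 1.6), (0, 1.6, -1.6), (0, -1.6, -1.6)]
            )
        ]
        st = ProteinStructure(
            [
                _res("ALA", "A", 1, [_atom("CA", "C", 0, 0, 0)]),
                _res("ALA", "A", 2, cage),
            ]
        )
        assert shrake_rupley_sasa(st)[("A", 1, "")] == pytest.approx(0.0, abs=1e-9)

    def test_quadrature_convergence(self):
        st = ProteinStructure([_res("ALA", "A", 1, [_atom("CA", "C", 0, 0, 0)])])
        a1 = shrake_rupley_sasa(st, n_points=960)[("A", 1, "")]
        a2 = shrake_rupley_sasa(st, n_points=1920)[("A", 1, "")]
        assert abs(a1 - a2) / a2 < 0.01

    def test_cross_check_against_independent_implementation(self, helix_structure):
        """Same algorithm in biotite (matched radii/points) agrees within 3%."""
        biotite_struct = pytest.importorskip("biotite.structure")
        from biotite.structure.io.pdb import PDBFile
        import io

        text = write_pdb(helix_structure)
        arr = PDBFile.read(io.StringIO(text)).get_structure(model=1)
        from ddgkit.structure import VDW_RADII, DEFAULT_VDW

        radii = np.array(
            [VDW_RADII.get(e.capitalize().upper(), DEFAULT_VDW) for e in arr.element]
        )
        ref = biotite_struct.sasa(arr, probe_radius=1.4, point_number=960,
                                  vdw_radii=radii)
        ref_per_res = {}
        for i in range(len(arr)):
            rid = ("A", int(arr.res_id[i]), "")
            ref_per_res[rid] = ref_per_res.get(rid, 0.0) + float(ref[i])
        ours = shrake_rupley_sasa(helix_structure)
        total_ours = sum(ours.values())
        total_ref = sum(ref_per_res.values())
        assert total_ours == pytest.approx(total_ref, rel=0.03)


class TestRSA:
    def test_zero_sasa_is_buried(self):
        rsa, label = relative_accessibility(0.0, "A")
        assert rsa == 0.0 and label == "buried"

    def test_max_asa_gives_one_exposed(self):
        rsa, label = relative_accessibility(MAX_ASA["W"], "W")
        assert rsa == pytest.approx(1.0) and label == "exposed"

    def test_threshold_boundary(self):
        max_a = MAX_ASA["A"]
        assert relative_accessibility(0.249 * max_a, "A")[1] == "buried"
        assert relative_accessibility(0.251 * max_a, "A")[1] == "exposed"

    def test_clip_at_1_2(self):
        assert relative_accessibility(10 * MAX_ASA["G"], "G")[0] == 1.2

    def test_unknown_residue_raises(self):
        with pytest.raises(KeyError):
            relative_accessibility(10.0, "X")


class TestSecondaryStructure:
    def test_alpha_helix_region(self):
        assert classify_phi_psi(-57.0, -47.0) == "alpha_helix"

    def test_beta_region(self):
        assert classify_phi_psi(-120.0, 130.0) == "extended_beta"

    def test_undefined_dihedral_is_loop(self):
        assert classify_phi_psi(None, -47.0) == "other_loop"

    def test_helix_fixture_interior_all_alpha(self, helix_structure):
        ss = dk.assign_secondary_structure(helix_structure)
        interior = helix_structure.residues[1:-1]
        assert all(ss[r.rid] == "alpha_helix" for r in interior)
        assert ss[helix_structure.residues[0].rid] == "other_loop"
        assert ss[helix_structure.residues[-1].rid] == "other_loop"

    def test_dihedrals_match_construction(self, helix_structure):
        d = backbone_dihedrals(helix_structure)
        phis = [p for p, s in d.values() if p is not None]
        psis = [s for p, s in d.values() if s is not None]
        assert np.allclose(phis, -57.0, atol=0.5)
        assert np.allclose(psis, -47.0, atol=0.5)


class TestGNM:
    def test_kirchhoff_rows_sum_to_zero(self, helix_structure):
        gamma, _ = gnm_kirchhoff(helix_structure)
        assert np.allclose(gamma.sum(axis=1), 0.0)

    def test_two_node_pseudo_inverse(self):
        st = ProteinStructure(
            [
                _res("ALA", "A", 1, [_atom("CA", "C", 0, 0, 0)]),
                _res("ALA", "A", 2, [_atom("CA", "C", 3.8, 0, 0)]),
            ]
        )
        gamma, _ = gnm_kirchhoff(st)
        assert np.array_equal(gamma, np.array([[1.0, -1.0], [-1.0, 1.0]]))
        diag = np.diag(np.linalg.pinv(gamma))
        assert np.allclose(diag, [0.25, 0.25])
        fluct = gnm_fluctuations(st)
        assert fluct[("A", 1, "")] == pytest.approx(fluct[("A", 2, "")])

    def test_invariance_under_rigid_motion(self, helix_structure):
        base = gnm_fluctuations(helix_structure)
        shifted = ProteinStructure(
            [
                Residue(
                    r.name3, r.chain_id, r.author_number, r.icode,
                    [Atom(a.name, a.element, a.coords + np.array([5.0, -3.0, 2.0]))
                     for a in r.atoms],
                )
                for r in helix_structure.residues
            ]
        )
        moved = gnm_fluctuations(shifted)
        for rid in base:
            assert moved[rid] == pytest.approx(base[rid], abs=1e-9)

    def test_fluctuations_nonnegative_unit_mean(self, helix_structure):
        fluct = gnm_fluctuations(helix_structure)
        vals = np.array(list(fluct.values()))
        assert (vals >= 0).all()
        assert vals.mean() == pytest.approx(1.0)

    def test_disconnected_graph_warns(self):
        st = ProteinStructure(
            [
                _res("ALA", "A", 1, [_atom("CA", "C", 0, 0, 0)]),
                _res("ALA", "A", 2, [_atom("CA", "C", 3.8, 0, 0)]),
                _res("ALA", "A", 3, [_atom("CA", "C", 100, 0, 0)]),
                _res("ALA", "A", 4, [_atom("CA", "C", 103.8, 0, 0)]),
            ]
        )
        with pytest.warns(UserWarning, match="components"):
            gnm_fluctuations(st)
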