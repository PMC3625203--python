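import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efmoscan.constants import vdw_radius
from efmoscan.system_model import (MolecularSystem, ParseError, detect_bonds,
                                   fragment_by_residue,
                                   interfragment_distance, parse_annotation,
                                   read_fragment_map, read_frames, read_pdb,
                                   read_xyz, write_fragment_map, write_frames)

from conftest import random_rotation_matrix, water_system


class TestXYZ:
    def test_water_xyz_roundtrip_ordering(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text("3\nwater\nO 0.0 0.0 0.0\nH 0.95 0.0 0.0\nH -0.24 0.92 0.0\n")
        s = read_xyz(p)
        assert s.n_atoms == 3
        assert s.elements() == ["O", "H", "H"]
        assert np.allclose(s.atoms[1].position, [0.95, 0, 0])

    def test_empty_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with pytest.raises(ParseError):
            read_xyz(p)

    @pytest.mark.parametrize("bad, match", [
        ("x\ncomment\n", "atom count"),
        ("1\nc\nO a b c\n", "non-numeric"),
        ("2\nc\nO 0 0 0\n", "atom rows"),
    ])
    def test_malformed_files_name_the_line(self, tmp_path, bad, match):
        p = tmp_path / "bad.xyz"
        p.write_text(bad)
        with pytest.raises(ParseError, match=match):
            read_xyz(p)

    def test_multiframe_selects_frame(self, tmp_path):
        p = tmp_path / "mf.xyz"
        p.write_text("1\nf0\nO 0 0 0\n1\nf1\nO 1 0 0\n")
        assert read_xyz(p).atoms[0].position[0] == 0.0
        assert read_xyz(p, frame=1).atoms[0].position[0] == 1.0
        with pytest.raises(ParseError):
            read_xyz(p, frame=5)

    def test_write_read_frames_roundtrip(self, tmp_path, five_waters):
        frames = []
        for k in range(3):
            s = five_waters.copy()
            s.set_coordinates(s.coordinates() + 0.1 * k)
            frames.append((s, {"R": -1.95 + k, "E": -10.0 + k}))
        p = tmp_path / "traj.xyz"
        write_frames(frames, p)
        back = read_frames(p)
        assert len(back) == 3
        for (s0, a0), (s1, a1) in zip(frames, back):
            assert np.abs(s0.coordinates() - s1.coordinates()).max() < 1e-6
            assert s0.elements() == s1.elements()
            assert a1["R"] == pytest.approx(a0["R"])
            assert a1["E"] == pytest.approx(a0["E"])

    def test_zero_frames_gives_empty_file(self, tmp_path):
        p = tmp_path / "none.xyz"
        write_frames([], p)
        assert p.read_text() == ""

    def test_roster_mismatch_rejected(self, tmp_path, five_waters,
                                      equilibrium_water):
        with pytest.raises(ValueError, match="roster"):
            write_frames([(five_waters, {}), (equilibrium_water, {})],
                         tmp_path / "x.xyz")

    def test_annotation_parse_back(self):
        assert parse_annotation("R= -1.95 E= -10.0") == {"R": -1.95, "E": -10.0}


class TestPDB:
    def test_three_residues_detected(self, gly_gly_pdb):
        s = read_pdb(gly_gly_pdb)
        assert s.n_atoms == 11
        assert len({a.residue_id for a in s.atoms}) == 3

    def test_element_from_atom_name_when_missing(self, tmp_path):
        text = ("ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
                "  1.00  0.00\nEND\n")
        p = tmp_path / "noelem.pdb"
        p.write_text(text)
        s = read_pdb(p)
        assert s.atoms[0].element == "C"

    def test_insertion_codes_split_residues(self, tmp_path):
        text = (
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      2  O   HOH A   1A      5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n")
        p = tmp_path / "icode.pdb"
        p.write_text(text)
        s = read_pdb(p)
        assert len({a.residue_id for a in s.atoms}) == 2

    def test_conect_records_become_bonds(self, tmp_path):
        text = (
            "HETATM    1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  C2  LIG A   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "CONECT    1    2\n"
            "END\n")
        p = tmp_path / "conect.pdb"
        p.write_text(text)
        s = read_pdb(p)
        assert s.bonds == {(0, 1)}


class TestBondsAndFragments:
    def test_water_monomer_bonds(self, equilibrium_water):
        assert equilibrium_water.bonds == {(0, 1), (0, 2)}

    def test_distant_waters_not_bonded(self):
        s = water_system([[0, 0, 0], [5.0, 0, 0]])
        inter = [b for b in s.bonds if (b[0] < 3) != (b[1] < 3)]
        assert inter == []

    def test_zero_scale_gives_no_bonds(self, equilibrium_water):
        bare = MolecularSystem([a for a in equilibrium_water.copy().atoms])
        detect_bonds(bare, scale=0.0)
        assert bare.bonds == set()

    def test_peptide_cut_shares_calpha(self, gly_gly_pdb):
        s = read_pdb(gly_gly_pdb)
        detect_bonds(s)
        fragment_by_residue(s)
        assert len(s.fragments) == 3
        shared = {i for f in s.fragments for i, _ in f.shared_atoms}
        assert shared == {1}          # CA of residue 1
        # carbonyl C and O of residue 1 moved into the second fragment
        assert 2 in s.fragments[1].atom_indices
        assert 3 in s.fragments[1].atom_indices
        s.validate_fragmentation()

    def test_isolated_waters_have_no_shared_atoms(self, five_waters):
        assert len(five_waters.fragments) == 5
        assert all(not f.shared_atoms for f in five_waters.fragments)
        five_waters.validate_fragmentation()

    def test_single_residue_is_identity(self, equilibrium_water):
        frag = equilibrium_water.fragments[0]
        assert frag.atom_indices == [0, 1, 2]
        assert frag.shared_atoms == []

    def test_partition_identity_on_chain(self):
        from efmoscan.synth import make_bonded_chain
        s = make_bonded_chain(5, seed=2)
        total = sum(len(f.atom_indices) for f in s.fragments)
        n_shared = sum(len(f.shared_atoms) for f in s.fragments) // 2
        assert total - n_shared == s.n_atoms
        assert n_shared == 4

    def test_fragment_map_roundtrip(self, tmp_path, gly_gly_pdb):
        s = read_pdb(gly_gly_pdb)
        detect_bonds(s)
        fragment_by_residue(s)
        p = tmp_path / "map.frag"
        write_fragment_map(s, p)
        s2 = read_pdb(gly_gly_pdb)
        detect_bonds(s2)
        read_fragment_map(s2, p)
        for f1, f2 in zip(s.fragments, s2.fragments):
            assert f1.atom_indices == f2.atom_indices
            assert f1.guest_atoms == f2.guest_atoms
            assert f1.net_charge == f2.net_charge


class TestInterfragmentDistance:
    def test_two_oxygens_at_vdw_contact(self):
        s = water_system([[0, 0, 0], [50, 0, 0]])
        # override: measure two bare O atoms 3.04 A apart
        from efmoscan.system_model import Atom, Fragment
        atoms = [Atom(0, "O", [0, 0, 0]), Atom(1, "O", [2 * vdw_radius("O"), 0, 0])]
        sys2 = MolecularSystem(atoms)
        f0 = Fragment(0, [0])
        f1 = Fragment(1, [1])
        sys2.fragments = [f0, f1]
        assert interfragment_distance(f0, f1, sys2) == pytest.approx(1.0)

    def test_coincident_atoms_give_zero(self):
        from efmoscan.system_model import Atom, Fragment
        atoms = [Atom(0, "O", [0, 0, 0]), Atom(1, "O", [0, 0, 0])]
        sys2 = MolecularSystem(atoms)
        f0, f1 = Fragment(0, [0]), Fragment(1, [1])
        sys2.fragments = [f0, f1]
        assert interfragment_distance(f0, f1, sys2) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetric_and_rigid_motion_invariant(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0, 8, (2, 3))
        while np.linalg.norm(centers[0] - centers[1]) < 2.0:
            centers = rng.uniform(0, 8, (2, 3))
        s = water_system(centers, seed=seed)
        I, J = s.fragments
        d_ij = interfragment_distance(I, J, s)
        d_ji = interfragment_distance(J, I, s)
        assert d_ij == pytest.approx(d_ji, abs=1e-12)
        # rigid transform
        R = random_rotation_matrix(rng)
        shift = rng.uniform(-5, 5, 3)
        s.set_coordinates(s.coordinates() @ R.T + shift)
        assert interfragment_distance(I, J, s) == pytest.approx(d_ij, abs=1e-9)

    def test_error_when_only_shared_atoms_remain(self):
        from efmoscan.system_model import Atom, Fragment
        atoms = [Atom(0, "C", [0, 0, 0]), Atom(1, "C", [1.5, 0, 0])]
        sys2 = MolecularSystem(atoms)
        f0 = Fragment(0, [0, 1], shared_atoms=[(0, 1), (1, 1)])
        f1 = Fragment(1, [0, 1], shared_atoms=[(0, 0), (1, 0)],
                      guest_atoms={0, 1})
        sys2.fragments = [f0, f1]
        with pytest.raises(ValueError, match="shared"):
            interfragment_distance(f0, f1, sys2)
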