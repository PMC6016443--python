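import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memint.molecular_model import (
    Atom,
    Frame,
    MoleculeKind,
    StructureParseError,
    Topology,
    TopologyError,
    Trajectory,
    UnsupportedBoxError,
    minimum_image,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from oracles import image_enumeration_distance

pos3 = st.lists(
    st.floats(-50.0, 50.0, allow_nan=False), min_size=3, max_size=3
)
box3 = st.lists(st.floats(5.0, 40.0, allow_nan=False), min_size=3, max_size=3)


class TestMinimumImage:
    def test_wrap_across_boundary(self):
        _, d = minimum_image([0, 0, 0], [9, 0, 0], [10, 10, 10])
        assert d == pytest.approx(1.0)

    def test_identity(self):
        _, d = minimum_image([3.0, 4.0, 5.0], [3.0, 4.0, 5.0], [10, 10, 10])
        assert d == 0.0

    def test_invalid_box(self):
        with pytest.raises(UnsupportedBoxError):
            minimum_image([0, 0, 0], [1, 1, 1], [0.0, 10, 10])

    def test_matches_image_enumeration(self):
        rng = np.random.default_rng(0)
        box = np.array([13.0, 17.0, 23.0])
        for _ in range(1000):
            a = rng.uniform(-30, 30, 3)
            b = rng.uniform(-30, 30, 3)
            _, d = minimum_image(a, b, box)
            # enumeration needs points reduced to the primary cell first
            expected = image_enumeration_distance(a % box, b % box, box)
            assert d == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(a=pos3, b=pos3, box=box3, shift=st.lists(st.integers(-3, 3), min_size=3, max_size=3))
    def test_symmetry_and_periodicity(self, a, b, box, shift):
        a, b, box = np.array(a), np.array(b), np.array(box)
        d_ab, r_ab = minimum_image(a, b, box)
        _, r_ba = minimum_image(b, a, box)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        _, r_shifted = minimum_image(a, b + np.array(shift) * box, box)
        assert r_ab == pytest.approx(r_shifted, abs=1e-6)
        assert np.all(d_ab >= -box / 2 - 1e-9) and np.all(d_ab < box / 2 + 1e-9)


class TestTopology:
    def test_duplicate_atom_ids_rejected(self):
        atoms = [
            Atom(1, "A", "A", 0, MoleculeKind.OTHER, -1, None, 0, 0.1, 2, False, False),
            Atom(1, "B", "B", 1, MoleculeKind.OTHER, -1, None, 0, 0.1, 2, False, False),
        ]
        with pytest.raises(TopologyError, match="duplicate"):
            Topology(atoms)

    def test_donor_without_hydrogen_rejected(self):
        atoms = [
            Atom(0, "N", "N", 0, MoleculeKind.OTHER, -1, None, 0, 0.1, 2, True, False)
        ]
        with pytest.raises(TopologyError, match="hydrogen"):
            Topology(atoms)

    def test_sidearm_only_on_polymer(self):
        atoms = [
            Atom(0, "P", "P", 0, MoleculeKind.POPE, -1, 3, 0, 0.1, 2, False, False)
        ]
        with pytest.raises(TopologyError, match="sidearm"):
            Topology(atoms)


WATER_PDB = """\
CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.960   0.000   0.000  1.00  0.00           H
ATOM      3  H2  HOH A   1      -0.240   0.930   0.000  1.00  0.00           H
END
"""

WATER_CHEM = """\
resname,atomname,charge,epsilon,rmin_half,is_donor,is_acceptor
HOH,O,-0.834,0.152,1.77,True,True
HOH,H1,0.417,0,0.22,False,False
HOH,H2,0.417,0,0.22,False,False
"""


class TestReadStructure:
    def test_water_donor_annotation(self, tmp_path):
        pdb = tmp_path / "water.pdb"
        pdb.write_text(WATER_PDB)
        chem = tmp_path / "chem.csv"
        chem.write_text(WATER_CHEM)
        top, frame = read_structure(pdb, chem)
        oxygen = top.atoms[0]
        assert oxygen.is_donor and oxygen.is_acceptor
        assert oxygen.bonded_hydrogens == (1, 2)
        assert frame.n_atoms == 3
        assert np.allclose(frame.box, 20.0)

    def test_synthetic_system_atom_count(self, default_system, chemistry_csv, tmp_path):
        # 90 PE x 7 beads + 38 PG x 9 beads + 4 chains x 12 monomers x 5 beads
        expected = 90 * 7 + 38 * 9 + 4 * 12 * 5
        assert default_system.topology.n_atoms == expected
        path = tmp_path / "sys.pdb"
        write_structure(default_system.topology, default_system.frame, path)
        top, _ = read_structure(path, chemistry_csv)
        assert top.n_atoms == expected

    def test_empty_file_rejected(self, tmp_path, chemistry_csv):
        path = tmp_path / "empty.pdb"
        path.touch()
        with pytest.raises(StructureParseError):
            read_structure(path, chemistry_csv)

    def test_unmapped_atoms_flagged_other(self, tmp_path):
        pdb = tmp_path / "water.pdb"
        pdb.write_text(WATER_PDB)
        chem = tmp_path / "chem.csv"
        chem.write_text(
            "resname,atomname,charge,epsilon,rmin_half,is_donor,is_acceptor\n"
            "HOH,O,-0.8,0.1,1.7,False,True\n"
        )
        with pytest.warns(UserWarning, match="OTHER"):
            top, _ = read_structure(pdb, chem)
        assert top.atoms[1].molecule_kind is MoleculeKind.OTHER
        assert top.atoms[1].charge == 0.0

    def test_triclinic_box_rejected(self, tmp_path, chemistry_csv):
        pdb = tmp_path / "tri.pdb"
        pdb.write_text(WATER_PDB.replace("90.00  90.00  90.00", "90.00  90.00  60.00"))
        chem = tmp_path / "chem.csv"
        chem.write_text(WATER_CHEM)
        with pytest.raises(UnsupportedBoxError, match="orthorhombic"):
            read_structure(pdb, chem)


class TestRoundTrip:
    def test_pdb_roundtrip_preserves_names_and_coords(
        self, default_system, chemistry_csv, tmp_path
    ):
        path = tmp_path / "sys.pdb"
        write_structure(default_system.topology, default_system.frame, path)
        top, frame = read_structure(path, chemistry_csv)
        assert [a.name for a in top.atoms] == [
            a.name for a in default_system.topology.atoms
        ]
        # PDB stores 3 decimals
        assert np.allclose(
            frame.coordinates, default_system.frame.coordinates, atol=1.5e-3
        )
        assert [a.sidearm_id for a in top.atoms] == [
            a.sidearm_id for a in default_system.topology.atoms
        ]
        assert [a.is_donor for a in top.atoms] == [
            a.is_donor for a in default_system.topology.atoms
        ]


class TestTrajectoryIO:
    @pytest.fixture()
    def traj(self, default_system):
        frames = [
            Frame(
                default_system.frame.coordinates + 0.1 * i,
                default_system.frame.box,
                time=float(i),
            )
            for i in range(5)
        ]
        return Trajectory(default_system.topology, frames)

    @pytest.mark.parametrize("suffix", ["pdb", "xyz"])
    def test_multiframe_roundtrip(self, traj, default_system, tmp_path, suffix):
        path = tmp_path / f"traj.{suffix}"
        write_trajectory(traj, path)
        back = read_trajectory(path, default_system.topology)
        assert len(back) == 5
        assert np.allclose(back.frames[0].box, default_system.frame.box, atol=1e-2)
        assert np.allclose(
            back.frames[3].coordinates, traj.frames[3].coordinates, atol=1.5e-3
        )

    def test_atom_count_mismatch(self, traj, tmp_path):
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        small = Topology(
            [
                Atom(0, "X", "X", 0, MoleculeKind.OTHER, -1, None, 0, 0.1, 2,
                     False, False)
            ]
        )
        with pytest.raises(ValueError, match="atoms"):
            read_trajectory(path, small)

    def test_xyz_without_box_rejected(self, tmp_path, default_system):
        path = tmp_path / "nobox.xyz"
        path.write_text("2\ncomment without dimensions\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(UnsupportedBoxError, match="box"):
            read_trajectory(path, default_system.topology)

    def test_frames_must_be_time_ordered(self, default_system):
        f = default_system.frame
        with pytest.raises(ValueError, match="time-ordered"):
            Trajectory(
                default_system.topology,
                [
                    Frame(f.coordinates, f.box, time=1.0),
                    Frame(f.coordinates, f.box, time=0.0),
                ],
            )
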