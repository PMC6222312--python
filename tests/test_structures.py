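"""Structure I/O, segment classification and geometry utilities."""

import numpy as np
import pytest

from skfield.structures import (AtomRecord, ChargedSystem, ParseError,
                                Segment, assign_charges, classify_segment,
                                read_structure, read_trajectory,
                                residue_min_distance, write_structure,
                                write_trajectory)
from skfield.synthetic_data import ToySpec, make_toy_polypeptide, \
    make_trajectory


def _tiny_pqr(tmp_path, rows):
    path = tmp_path / "tiny.pqr"
    path.write_text("\n".join(rows) + "\n")
    return path


class TestReadStructure:
    def test_pqr_charges_in_file_order(self, tmp_path):
        path = _tiny_pqr(tmp_path, [
            "ATOM 1 N ALA A 1 0.0 0.0 0.0 0.5 1.5",
            "ATOM 2 CA ALA A 1 1.0 0.0 0.0 -0.5 1.7",
            "ATOM 3 C ALA A 1 2.0 0.0 0.0 0.0 1.7",
        ])
        system = read_structure(path, dialect="pqr")
        assert [a.charge for a in system.atoms] == [0.5, -0.5, 0.0]
        assert [a.serial for a in system.atoms] == [1, 2, 3]

    def test_water_residues_classified_as_solvent(self, tmp_path):
        pdb = tmp_path / "w.pdb"
        pdb.write_text(
            "ATOM      1  O   HOH A   1      0.000   0.000   0.000"
            "  1.00  0.00           O\n"
            "ATOM      2  CA  ALA A   2      3.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "END\n")
        system = read_structure(pdb, dialect="pdb")
        assert system.atoms[0].segment == Segment.SOLVENT
        assert system.atoms[1].segment == Segment.PROTEIN
        assert all(a.charge == 0.0 for a in system.atoms)

    def test_pqr_round_trip_preserves_coords_and_charges(self, tmp_path,
                                                         toy_peptide):
        path = tmp_path / "pep.pqr"
        write_structure(toy_peptide, path, dialect="pqr")
        back = read_structure(path, dialect="pqr")
        np.testing.assert_allclose(back.coords, toy_peptide.coords,
                                   atol=1e-6)
        np.testing.assert_allclose(back.charges, toy_peptide.charges,
                                   atol=1e-6)
        assert [a.segment for a in back.atoms] == \
            [a.segment for a in toy_peptide.atoms]

    def test_malformed_row_names_line(self, tmp_path):
        path = _tiny_pqr(tmp_path, [
            "ATOM 1 N ALA A 1 0.0 0.0 0.0 0.5 1.5",
            "ATOM 2 CA ALA A 1 not-a-number 0.0 0.0 -0.5 1.7",
        ])
        with pytest.raises(ParseError, match="line 2"):
            read_structure(path, dialect="pqr")

    def test_duplicate_serial_rejected(self, tmp_path):
        path = _tiny_pqr(tmp_path, [
            "ATOM 7 N ALA A 1 0.0 0.0 0.0 0.5 1.5",
            "ATOM 7 CA ALA A 1 1.0 0.0 0.0 -0.5 1.7",
        ])
        with pytest.raises(ValueError, match="duplicate"):
            read_structure(path, dialect="pqr")

    def test_classification_covers_every_atom(self, probe_scene):
        system, _, _ = probe_scene
        assert all(isinstance(a.segment, Segment) for a in system.atoms)

    @pytest.mark.parametrize("name,expected", [
        ("HOH", Segment.SOLVENT), ("WAT", Segment.SOLVENT),
        ("NA+", Segment.ION), ("MG", Segment.ION),
        ("GLY", Segment.PROTEIN), ("19N", Segment.LIGAND),
    ])
    def test_classification_rules(self, name, expected):
        assert classify_segment(name) == expected

    def test_classification_override(self):
        assert classify_segment("XYZ", {"XYZ": Segment.ION}) == Segment.ION


class TestCrossCheckWithMDAnalysis:
    """Our writers against an independent reader."""

    def test_written_pqr_read_back_by_mdanalysis(self, tmp_path, toy_peptide):
        mda = pytest.importorskip("MDAnalysis")
        path = tmp_path / "pep.pqr"
        write_structure(toy_peptide, path, dialect="pqr")
        u = mda.Universe(str(path))
        np.testing.assert_allclose(u.atoms.positions,
                                   toy_peptide.coords, atol=1e-3)
        np.testing.assert_allclose(u.atoms.charges,
                                   toy_peptide.charges, atol=1e-4)

    def test_written_trajectory_read_back_by_mdanalysis(self, tmp_path,
                                                        toy_peptide):
        mda = pytest.importorskip("MDAnalysis")
        spec = ToySpec(n_residues=8, jitter_sigma=0.1, n_frames=4, seed=5)
        traj = make_trajectory(toy_peptide, spec)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        u = mda.Universe(str(path))
        assert len(u.trajectory) == 4
        for ts, frame in zip(u.trajectory, traj.frames):
            np.testing.assert_allclose(u.atoms.positions, frame, atol=1e-3)


class TestAssignCharges:
    def test_zero_table_gives_zero_total(self, toy_peptide):
        table = {(a.residue_name, a.name): 0.0 for a in toy_peptide.atoms}
        out = assign_charges(toy_peptide, table)
        assert out.charges.sum() == 0.0

    def test_per_residue_design_sums(self, toy_peptide):
        """A per-atom table reproduces designed per-residue net charges."""
        table = {("ALA", name): q for name, _, _, q in
                 __import__("skfield.synthetic_data",
                            fromlist=["RESIDUE_TEMPLATE"]).RESIDUE_TEMPLATE}
        out = assign_charges(toy_peptide, table)
        for key in out.residue_keys():
            idx = out.residue_atoms(key)
            assert sum(out.atoms[i].charge for i in idx) == pytest.approx(0.0,
                                                                          abs=1e-12)

    def test_missing_entry_lists_pairs(self, toy_peptide):
        table = {("ALA", "N"): 0.0}
        with pytest.raises(KeyError, match="ALA:CA"):
            assign_charges(toy_peptide, table)

    def test_additivity_of_net_charges(self):
        spec = ToySpec(n_residues=8, residue_net_charges=[-1.0] * 8)
        system = make_toy_polypeptide(spec)
        assert system.charges.sum() == pytest.approx(-8.0, abs=1e-12)


class TestReadTrajectory:
    def test_single_model_file(self, tmp_path, toy_peptide):
        path = tmp_path / "one.pdb"
        write_structure(toy_peptide, path, dialect="pdb")
        traj = read_trajectory(path, toy_peptide)
        assert traj.n_frames == 1

    def test_round_trip_of_generated_trajectory(self, tmp_path, toy_peptide):
        spec = ToySpec(n_residues=8, jitter_sigma=0.2, n_frames=10, seed=2)
        traj = make_trajectory(toy_peptide, spec)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, toy_peptide)
        assert back.n_frames == 10
        for a, b in zip(back.frames, traj.frames):
            np.testing.assert_allclose(a, b, atol=1e-3)

    def test_atom_count_mismatch_names_model(self, tmp_path, toy_peptide):
        spec = ToySpec(n_residues=8, n_frames=2)
        traj = make_trajectory(toy_peptide, spec)
        path = tmp_path / "bad.pdb"
        write_trajectory(traj, path)
        lines = path.read_text().splitlines()
        # drop one ATOM line from the second model
        second_model = [i for i, l in enumerate(lines)
                        if l.startswith("MODEL")][1]
        del lines[second_model + 1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="model 2"):
            read_trajectory(path, toy_peptide)


class TestResidueMinDistance:
    def test_three_four_five_triangle(self, random_charged_system):
        system = random_charged_system(2, seed=0)
        system.atoms[0].coord = np.array([0.0, 0.0, 0.0])
        system.atoms[1].coord = np.array([3.0, 4.0, 0.0])
        d = residue_min_distance(system, system.coords, [0], [1])
        assert d == pytest.approx(5.0, abs=1e-12)

    def test_translation_shifts_axis_aligned_distance(self,
                                                      random_charged_system):
        system = random_charged_system(2, seed=0)
        system.atoms[0].coord = np.array([0.0, 0.0, 0.0])
        system.atoms[1].coord = np.array([2.0, 0.0, 0.0])
        frame = system.coords
        d0 = residue_min_distance(system, frame, [0], [1])
        frame2 = frame.copy()
        frame2[1, 0] += 1.5
        assert residue_min_distance(system, frame2, [0], [1]) == \
            pytest.approx(d0 + 1.5, abs=1e-12)

    def test_matches_brute_force_on_random_groups(self,
                                                  random_charged_system):
        system = random_charged_system(10, seed=42)
        frame = system.coords
        ga, gb = list(range(5)), list(range(5, 10))
        expected = min(np.linalg.norm(frame[i] - frame[j])
                       for i in ga for j in gb)
        assert residue_min_distance(system, frame, ga, gb) == \
            pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_nonnegativity(self, random_charged_system):
        system = random_charged_system(8, seed=1)
        frame = system.coords
        ga, gb = [0, 1, 2], [5, 6, 7]
        dab = residue_min_distance(system, frame, ga, gb)
        dba = residue_min_distance(system, frame, gb, ga)
        assert dab == dba >= 0

    def test_identical_groups_rejected(self, random_charged_system):
        system = random_charged_system(4, seed=2)
        with pytest.raises(ValueError, match="disjoint"):
            residue_min_distance(system, system.coords, [0, 1], [1, 2])
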