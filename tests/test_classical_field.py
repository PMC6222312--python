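"""Point-charge potentials, bond fields, decomposition, H-bond analysis."""

import numpy as np
import pytest

from skfield.classical_field import (ExclusionSet, FieldRecord, bond_field,
                                     decompose_field, esp_at_point,
                                     field_series, hbond_series)
from skfield.constants import COULOMB_K_V_ANG
from skfield.structures import AtomRecord, ChargedSystem, ProbeBond, Segment, \
    Trajectory
from skfield.synthetic_data import (ToySpec, make_field_benchmark,
                                    make_trajectory)


def _point_system(charges_coords, eps_eff=1.0):
    atoms = [
        AtomRecord(serial=i + 1, name=f"Q{i}", element="C", residue_index=1,
                   residue_name="RND", segment=Segment.ION,
                   coord=np.asarray(xyz, float), charge=q)
        for i, (q, xyz) in enumerate(charges_coords)
    ]
    return ChargedSystem(atoms=atoms, eps_eff=eps_eff)


class TestEspAtPoint:
    def test_unit_charge_at_one_angstrom(self):
        system = _point_system([(1.0, (0, 0, 0))])
        v = esp_at_point(system, np.array([1.0, 0, 0]))
        assert v == pytest.approx(COULOMB_K_V_ANG, rel=1e-12)

    def test_empty_source_set_gives_zero(self):
        system = _point_system([(1.0, (0, 0, 0))])
        excl = ExclusionSet(indices=frozenset({0}))
        assert esp_at_point(system, np.array([1.0, 0, 0]), excl) == 0.0

    def test_symmetric_pair_cancels(self):
        system = _point_system([(1.0, (1, 0, 0)), (-1.0, (-1, 0, 0))])
        assert esp_at_point(system, np.zeros(3)) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_singular_point_names_atom(self):
        system = _point_system([(1.0, (0, 0, 0))])
        with pytest.raises(ValueError, match="atom 1"):
            esp_at_point(system, np.array([0.0, 0.0, 1e-9]))

    def test_eps_eff_divides_potential(self):
        a = _point_system([(1.0, (0, 0, 0))], eps_eff=1.0)
        b = _point_system([(1.0, (0, 0, 0))], eps_eff=2.0)
        p = np.array([2.0, 0, 0])
        assert esp_at_point(b, p) == pytest.approx(esp_at_point(a, p) / 2,
                                                   rel=1e-12)


class TestBondField:
    def test_single_charge_benchmark(self, single_charge_scene):
        system, probe, analytic = single_charge_scene
        rec = bond_field(system, probe, ExclusionSet.from_probe(probe))
        assert rec.field == pytest.approx(analytic, rel=1e-12)

    def test_no_charges_gives_zero(self):
        system = _point_system([(0.0, (0, 0, 0)),
                                (0.0, (3, 0, 0)), (0.0, (4, 0, 0))])
        probe = ProbeBond(1, 2)
        rec = bond_field(system, probe, ExclusionSet.from_probe(probe))
        assert rec.field == 0.0

    def test_excluded_ring_contributes_nothing(self, probe_scene):
        """With every protein charge zeroed, only ring/tail charges remain;
        the default exclusion removes the ring, so the field equals the
        tail-only field."""
        system, probe, excl = probe_scene
        protein = system.segment_atoms(Segment.PROTEIN)
        for i in protein:
            system.atoms[i].charge = 0.0
        rec = bond_field(system, probe, excl)
        tail = np.setdiff1d(system.segment_atoms(Segment.LIGAND),
                            np.asarray(sorted(excl.indices)))
        rec_tail = bond_field(system, probe, excl, subset=tail)
        assert rec.field == pytest.approx(rec_tail.field, rel=1e-12)

    def test_offset_must_stay_inside_bond(self, single_charge_scene):
        system, probe, _ = single_charge_scene
        with pytest.raises(ValueError, match="offset"):
            bond_field(system, probe, ExclusionSet.from_probe(probe),
                       offset=0.5)

    def test_record_internal_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FieldRecord(phi_c=1.0, phi_o=0.0, length=1.0, field=50.0)

    def test_finite_difference_matches_coulomb_field(self):
        """-(phi(p+h*u) - phi(p-h*u))/2h converges to the analytic Coulomb
        field projection as h shrinks."""
        system = _point_system([(1.0, (0, 0, 0))])
        p = np.array([3.0, 0, 0])
        u = np.array([1.0, 0, 0])
        analytic = COULOMB_K_V_ANG / 9.0  # k q / r^2, pointing along +x, V/Å
        errs = []
        for h in (1e-2, 1e-3, 1e-4):
            fd = -(esp_at_point(system, p + h * u)
                   - esp_at_point(system, p - h * u)) / (2 * h)
            errs.append(abs(fd - analytic))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-8


class TestLinearityProperties:
    def test_union_field_is_sum_of_fields(self, random_charged_system):
        system = random_charged_system(12, seed=3)
        probe_atoms = [
            AtomRecord(serial=100, name="C1", element="C", residue_index=99,
                       residue_name="PRB", segment=Segment.LIGAND,
                       coord=np.array([20.0, 0, 0]), charge=0.0),
            AtomRecord(serial=101, name="O1", element="O", residue_index=99,
                       residue_name="PRB", segment=Segment.LIGAND,
                       coord=np.array([21.0, 0, 0]), charge=0.0),
        ]
        system = ChargedSystem(atoms=system.atoms + probe_atoms)
        probe = ProbeBond(12, 13)
        excl = ExclusionSet.from_probe(probe)
        total = bond_field(system, probe, excl).field
        parts = sum(
            bond_field(system, probe, excl, subset=[i]).field
            for i in range(12))
        assert parts == pytest.approx(total, rel=1e-10)

    def test_doubling_charges_doubles_field(self, single_charge_scene):
        system, probe, _ = single_charge_scene
        excl = ExclusionSet.from_probe(probe)
        f1 = bond_field(system, probe, excl).field
        for a in system.atoms:
            a.charge *= 2
        assert bond_field(system, probe, excl).field == pytest.approx(
            2 * f1, rel=1e-12)

    def test_eps_eff_halves_field(self, single_charge_scene):
        system, probe, _ = single_charge_scene
        excl = ExclusionSet.from_probe(probe)
        f1 = bond_field(system, probe, excl).field
        system.eps_eff = 2.0
        assert bond_field(system, probe, excl).field == pytest.approx(
            f1 / 2, rel=1e-12)


class TestFieldSeries:
    def test_rigid_trajectory_fields_constant(self, single_charge_scene):
        system, probe, analytic = single_charge_scene
        traj = Trajectory(topology=system,
                          frames=[system.coords] * 4)
        series = field_series(traj, probe, ExclusionSet.from_probe(probe))
        assert all(r.field == pytest.approx(analytic, rel=1e-12)
                   for r in series.records)
        assert series.mean == pytest.approx(analytic, rel=1e-12)

    def test_mean_is_arithmetic_average(self, single_charge_scene):
        system, probe, _ = single_charge_scene
        rng = np.random.default_rng(0)
        frames = [system.coords + rng.normal(0, 0.05, system.coords.shape)
                  for _ in range(6)]
        traj = Trajectory(topology=system, frames=frames)
        series = field_series(traj, probe, ExclusionSet.from_probe(probe))
        assert series.mean == pytest.approx(
            np.mean([r.field for r in series.records]), rel=1e-12)

    def test_jittered_capacitor_mean_within_sampling_bound(self):
        """The trajectory mean recovers the scene's reference field within
        three standard errors of the jittered samples."""
        system, probe, _ = make_field_benchmark(
            "capacitor", half_width=3.0, spacing=0.2, z_plate=0.5,
            q_site=4e-3)
        excl = ExclusionSet.from_probe(probe)
        truth = bond_field(system, probe, excl).field
        # jitter small against the charge-to-point distances so the 1/r
        # convexity bias stays inside the sampling band
        spec = ToySpec(n_residues=3, jitter_sigma=0.002, n_frames=200, seed=8)
        traj = make_trajectory(system, spec)
        series = field_series(traj, probe, excl)
        assert abs(series.mean - truth) < 3 * max(series.std_error, 1e-12)


class TestDecomposeField:
    @pytest.mark.parametrize("variant,expected_sum", [
        ("WT", -125.0), ("D103N", -111.0), ("Y16S", -75.0),
        ("D103L", -72.0),
    ])
    def test_worked_ksi_three_residue_sums(self, variant, expected_sum):
        """The published per-residue decomposition reproduces the printed
        three-residue sums for every ketosteroid-isomerase variant."""
        from skfield.examples import ksi_residue_fields
        fields = ksi_residue_fields(variant)
        total = fields["RES 16"] + fields["RES 103"] + fields["RES 40"]
        assert total == pytest.approx(expected_sum, abs=1e-12)

    def test_single_group_equals_total(self, probe_scene):
        system, probe, excl = probe_scene
        included = excl.included(system)
        dec = decompose_field(system, probe, excl,
                              {"all": included.tolist()})
        assert dec["all"].field == pytest.approx(dec["total"].field,
                                                 rel=1e-12)

    def test_random_partition_matches_per_atom_regrouping(self, probe_scene):
        system, probe, excl = probe_scene
        included = excl.included(system)
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 3, included.size)
        groups = {f"g{k}": included[labels == k].tolist() for k in range(3)}
        groups = {k: v for k, v in groups.items() if v}
        dec = decompose_field(system, probe, excl, groups)
        for label, idx in groups.items():
            brute = sum(bond_field(system, probe, excl, subset=[i]).field
                        for i in idx)
            assert dec[label].field == pytest.approx(brute, rel=1e-9)
        assert sum(dec[g].field for g in groups) == pytest.approx(
            dec["total"].field, rel=1e-9)

    def test_overlapping_groups_rejected(self, probe_scene):
        system, probe, excl = probe_scene
        included = excl.included(system).tolist()
        with pytest.raises(ValueError, match="overlap"):
            decompose_field(system, probe, excl,
                            {"a": included, "b": included[:1]})


class TestHBondSeries:
    def _const_traj(self, system, d, donor=0, acceptor=1, n=10):
        frames = []
        for _ in range(n):
            f = system.coords.copy()
            f[acceptor] = f[donor] + np.array([d, 0, 0])
            frames.append(f)
        return Trajectory(topology=system, frames=frames)

    def test_constant_short_distance_fully_occupied(self,
                                                    random_charged_system):
        system = random_charged_system(4, seed=0)
        traj = self._const_traj(system, 3.0)
        [res] = hbond_series(traj, [(0, 1)])
        assert res.occupancy == 1.0

    def test_constant_long_distance_never_occupied(self,
                                                   random_charged_system):
        system = random_charged_system(4, seed=0)
        traj = self._const_traj(system, 3.6)
        [res] = hbond_series(traj, [(0, 1)])
        assert res.occupancy == 0.0

    def test_two_state_occupancy_recovered(self, toy_peptide):
        from skfield.synthetic_data import HBondModel
        hb = HBondModel(r_bound=2.8, r_broken=5.2, p_bound=0.7, seed=13,
                        donor_index=4, acceptor_index=35)
        spec = ToySpec(n_residues=8, n_frames=5000, hbond_model=hb)
        traj = make_trajectory(toy_peptide, spec)
        [res] = hbond_series(traj, [(4, 35)], cutoff=3.5)
        assert abs(res.occupancy - 0.7) < 0.02

    def test_histogram_covers_all_frames(self, toy_peptide):
        from skfield.synthetic_data import HBondModel
        hb = HBondModel(p_bound=0.5, seed=1, donor_index=4,
                        acceptor_index=35)
        spec = ToySpec(n_residues=8, n_frames=400, hbond_model=hb)
        traj = make_trajectory(toy_peptide, spec)
        [res] = hbond_series(traj, [(4, 35)])
        counts, edges = res.histogram()
        assert counts.sum() == 400
        assert np.allclose(np.diff(edges), 0.1)

    def test_identical_atoms_rejected(self, toy_peptide):
        traj = Trajectory(topology=toy_peptide, frames=[toy_peptide.coords])
        with pytest.raises(ValueError, match="distinct"):
            hbond_series(traj, [(3, 3)])
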