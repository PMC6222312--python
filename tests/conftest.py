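import numpy as np
import pytest

from skfield.classical_field import ExclusionSet
from skfield.synthetic_data import (HBondModel, ToySpec, make_field_benchmark,
                                    make_probe_system, make_toy_polypeptide,
                                    make_trajectory)


@pytest.fixture
def toy_spec():
    return ToySpec(n_residues=8,
                   residue_net_charges=[0.0, -1.0, 0.0, 1.0, 0.0, -1.0, 0.0,
                                        0.0],
                   geometry="extended", seed=7)


@pytest.fixture
def toy_peptide(toy_spec):
    return make_toy_polypeptide(toy_spec)


@pytest.fixture
def hairpin_peptide():
    spec = ToySpec(n_residues=8,
                   residue_net_charges=[0.2, -0.5, 0.0, 0.3, 0.0, -0.5, 0.1,
                                        0.4],
                   geometry="hairpin", seed=3)
    return make_toy_polypeptide(spec)


@pytest.fixture
def probe_scene():
    """Toy peptide + ring-bearing probe ligand, with the canonical
    exclusion set."""
    spec = ToySpec(n_residues=6,
                   residue_net_charges=[0.0, -1.0, 0.5, 0.0, 0.5, 0.0],
                   geometry="extended", seed=11)
    system, probe, ring_excl = make_probe_system(spec, ring=True)
    excl = ExclusionSet.from_probe(probe,
                                   ring_indices=[i for i in ring_excl
                                                 if i not in
                                                 (probe.c_index,
                                                  probe.o_index)])
    return system, probe, excl


@pytest.fixture
def single_charge_scene():
    return make_field_benchmark("single_charge")


@pytest.fixture
def random_charged_system():
    """Factory for random small charged systems (no structure semantics)."""
    from skfield.structures import AtomRecord, ChargedSystem, Segment

    def _make(n, seed, spread=10.0):
        rng = np.random.default_rng(seed)
        atoms = [
            AtomRecord(serial=i + 1, name=f"Q{i}", element="C",
                       residue_index=1 + i // 4, residue_name="RND",
                       segment=Segment.LIGAND,
                       coord=rng.uniform(-spread, spread, 3),
                       charge=float(rng.uniform(-1, 1)))
            for i in range(n)
        ]
        return ChargedSystem(atoms=atoms)

    return _make
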