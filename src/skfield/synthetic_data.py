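"""Synthetic charged structures, probe ligands and trajectories.

Every downstream stage of the pipeline (classical fields, fragmentation,
fragment-assembled potentials, analytics) is exercised on structures built
here, with ground truth known by construction:

* :func:`make_toy_polypeptide` — an idealized polypeptide of 5-atom model
  residues (N, CA, C, O and a side-chain centroid CB) with designed
  per-residue net charges, in an extended, helix-like or hairpin geometry.
* :func:`make_probe_ligand` — a carbonyl C=O probe (1.23 Å), optionally fused
  to a neutral six-membered ring, mimicking a steroid-like product analogue.
* :func:`make_trajectory` — i.i.d. Gaussian positional jitter around the
  reference structure, optionally with a designed two-state hydrogen-bond
  donor–acceptor distance (bound/broken with probability ``p_bound``,
  independent frames, hence exactly binomial occupancy).
* :func:`make_field_benchmark` — scenes whose probe-bond field has a closed
  form (single charge, symmetric dipole, parallel-plate capacitor).

All generators are deterministic functions of their spec and seed; per-stream
seeds are derived from the global seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import COULOMB_K_V_ANG, V_PER_ANG_TO_MV_PER_CM
from .structures import (AtomRecord, ChargedSystem, ProbeBond, Segment,
                         Trajectory, merge_systems)

__all__ = [
    "ToySpec",
    "HBondModel",
    "make_toy_polypeptide",
    "make_probe_ligand",
    "make_trajectory",
    "make_field_benchmark",
    "RESIDUE_TEMPLATE",
]

# 5-atom model residue: (name, element, offset within residue frame, base charge).
# Base charges sum to zero; the designed residue net charge is added to CB.
# With a 3.8 Å repeat the peptide C(i)->N(i+1) bond comes out at 1.33 Å.
# Named ALA so segment classification survives a file round-trip.
RESIDUE_TEMPLATE = (
    ("N", "N", np.array([0.00, 0.00, 0.00]), -0.42),
    ("CA", "C", np.array([1.26, 0.74, 0.00]), 0.02),
    ("CB", "C", np.array([1.26, 2.24, 0.00]), 0.25),
    ("C", "C", np.array([2.47, 0.00, 0.00]), 0.60),
    ("O", "O", np.array([2.72, -1.20, 0.00]), -0.45),
)

_RESIDUE_SPACING = 3.8  # Å along the chain axis


@dataclass
class HBondModel:
    """Two-state donor–acceptor distance model for a designed H-bond.

    Each frame independently draws bound (distance ``r_bound``) with
    probability ``p_bound``, else broken (``r_broken``).  The acceptor atom is
    placed on the (jittered) donor->acceptor axis at the drawn distance, so the
    realized distance is exact and occupancy statistics are exactly binomial.
    """

    r_bound: float = 2.8
    r_broken: float = 5.2
    p_bound: float = 0.7
    seed: int = 0
    donor_index: Optional[int] = None
    acceptor_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bound <= 1.0:
            raise ValueError("p_bound must lie in [0, 1]")


@dataclass
class ToySpec:
    """Parameters of the toy generators.

    ``jitter_sigma`` is the per-coordinate Gaussian displacement (Å) applied
    independently to every atom in every frame.
    """

    n_residues: int = 8
    residue_net_charges: Optional[list[float]] = None
    geometry: str = "extended"  # extended | helixlike | hairpin
    seed: int = 0
    jitter_sigma: float = 0.0
    n_frames: int = 1
    hbond_model: Optional[HBondModel] = None

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3 (interior residues are "
                             "required by the fragmentation index ranges)")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.residue_net_charges is None:
            self.residue_net_charges = [0.0] * self.n_residues
        if len(self.residue_net_charges) != self.n_residues:
            raise ValueError("residue_net_charges length must equal n_residues")
        if self.geometry not in ("extended", "helixlike", "hairpin"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _residue_frame(i: int, n: int, geometry: str):
    """Origin and (x̂, ŷ, ẑ) axes of residue i's local frame."""
    ident = np.eye(3)
    if geometry == "extended":
        return np.array([_RESIDUE_SPACING * i, 0.0, 0.0]), ident
    if geometry == "helixlike":
        # loose helix: 1.5 Å rise, 100 deg twist, 2.3 Å radius
        theta = np.deg2rad(100.0) * i
        origin = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        return origin, ident
    # hairpin: two antiparallel extended strands separated by 5.7 Å in y,
    # bringing facing residues within ~3.5 Å (heavy-atom minimum).
    half = (n + 1) // 2
    if i < half:
        return np.array([_RESIDUE_SPACING * i, 0.0, 0.0]), ident
    flip = np.diag([-1.0, 1.0, 1.0])
    origin = np.array([_RESIDUE_SPACING * (2 * half - 1 - i), 5.7, 0.0])
    return origin, flip


def make_toy_polypeptide(spec: ToySpec) -> ChargedSystem:
    """Build an idealized polypeptide with designed per-residue net charges.

    Residues are rigid copies of :data:`RESIDUE_TEMPLATE`; per-residue charge
    sums equal ``spec.residue_net_charges`` exactly (the net charge rides on
    the side-chain centroid).  Deterministic: the geometry contains no random
    component, so identical specs give bit-identical systems.
    """
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(spec.n_residues):
        origin, axes = _residue_frame(i, spec.n_residues, spec.geometry)
        for name, elem, offset, q0 in RESIDUE_TEMPLATE:
            q = q0 + (spec.residue_net_charges[i] if name == "CB" else 0.0)
            atoms.append(AtomRecord(
                serial=serial, name=name, element=elem,
                residue_index=i + 1, residue_name="ALA",
                segment=Segment.PROTEIN,
                coord=origin + axes @ offset, charge=q))
            serial += 1
    return ChargedSystem(atoms=atoms)


def make_probe_ligand(position: np.ndarray,
                      direction: np.ndarray,
                      ring: bool = False):
    """Build a ligand fragment carrying a carbonyl probe.

    The carbonyl C sits at ``position`` with O 1.23 Å away along
    ``direction``.  With ``ring=True`` a neutral six-membered ring is fused
    behind the carbonyl (the probe C bonds to one ring vertex) plus two small
    tail atoms, mimicking a steroid-like scaffold.

    Returns ``(fragment, probe, exclusion_indices)`` where ``exclusion_indices``
    (into the fragment) is the canonical ESP exclusion set: probe C, probe O
    and every ring atom (8 atoms when ``ring=True``, else 2).
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("probe direction must be a nonzero vector")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("probe direction must be a unit vector")
    position = np.asarray(position, dtype=float)

    atoms: list[AtomRecord] = []

    def _add(name, elem, coord, q):
        atoms.append(AtomRecord(
            serial=len(atoms) + 1, name=name, element=elem,
            residue_index=1, residue_name="LIG", segment=Segment.LIGAND,
            coord=coord, charge=q))

    _add("C1", "C", position, 0.45)
    _add("O1", "O", position + 1.23 * direction, -0.50)
    exclusion = [0, 1]

    if ring:
        # ring plane: span direction and a perpendicular axis
        perp = np.array([0.0, 0.0, 1.0])
        if abs(direction @ perp) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp = perp - (perp @ direction) * direction
        perp /= np.linalg.norm(perp)
        center = position - 2.0 * direction
        ring_q = (0.1, -0.1, 0.1, -0.1, 0.1, -0.1)  # neutral ring
        for k in range(6):
            ang = np.pi * k / 3.0
            coord = center + 1.4 * (np.cos(ang) * direction + np.sin(ang) * perp)
            _add(f"CR{k + 1}", "C", coord, ring_q[k])
            exclusion.append(len(atoms) - 1)
        # two tail atoms outside the exclusion set (classical amendment source)
        _add("CT1", "C", center - 1.5 * direction + 1.2 * perp, 0.12)
        _add("CT2", "C", center - 1.5 * direction - 1.2 * perp, -0.12)

    fragment = ChargedSystem(atoms=atoms)
    probe = ProbeBond(c_index=0, o_index=1)
    return fragment, probe, exclusion


def make_trajectory(system: ChargedSystem, spec: ToySpec) -> Trajectory:
    """Jittered frames around ``system``'s coordinates, with an optional
    designed two-state H-bond distance.

    Seed streams: jitter uses ``spec.seed + 1``, the H-bond switching process
    uses ``hbond_model.seed`` (derived as ``spec.seed + 2`` by the CLI when
    unset).  Frames are independent by construction.
    """
    ref = system.coords
    rng = np.random.default_rng(spec.seed + 1)
    frames: list[np.ndarray] = []
    hb = spec.hbond_model
    if hb is not None:
        donor = hb.donor_index
        acceptor = hb.acceptor_index
        if donor is None:
            donor = int(system.atom_index(1, "O"))
        if acceptor is None:
            acceptor = int(system.atom_index(system.atoms[-1].residue_index, "N",
                                             segment=system.atoms[-1].segment))
        if donor == acceptor:
            raise ValueError("H-bond donor and acceptor must differ")
        hb_rng = np.random.default_rng(hb.seed)
        axis = ref[acceptor] - ref[donor]
        axis_norm = np.linalg.norm(axis)
        if axis_norm < 1e-12:
            raise ValueError("degenerate donor-acceptor axis")
        axis = axis / axis_norm
    for _ in range(spec.n_frames):
        frame = ref + (rng.normal(0.0, spec.jitter_sigma, ref.shape)
                       if spec.jitter_sigma > 0 else 0.0)
        if hb is not None:
            r = hb.r_bound if hb_rng.random() < hb.p_bound else hb.r_broken
            frame[acceptor] = frame[donor] + r * axis
        frames.append(np.asarray(frame, dtype=float))
    return Trajectory(topology=system, frames=frames)


def make_field_benchmark(kind: str, **kwargs):
    """Analytic-field benchmark scenes.

    Returns ``(system, probe, analytic_field_MV_cm)``; the probe atoms carry
    zero charge and form the canonical exclusion set ``[c_index, o_index]``.

    kinds
    -----
    ``single_charge``
        +1 e at the origin, probe C at (3,0,0), O at (4,0,0).  Closed form:
        14.399645 × (1/3 − 1/4) V over a 1 Å bond ≈ +120.0 MV/cm.
    ``dipole_pair``
        ±1 e at (0,0,±1); the probe lies in the midplane, where the potential
        vanishes identically: field 0.
    ``capacitor``
        Two parallel square sheets of discrete charges.  The default geometry
        (half-width 25 Å, plates at z=±0.3 Å, 0.15 Å lattice, ±1e-4 e per
        site) keeps the plate half-width large against both the gap and the
        lattice spacing, so the infinite-sheet formula E = σ/ε₀ holds at the
        center to within 2% (edge effect ≈ 1.1%).
    """
    def _probe_atoms(start, rc, ro):
        return [
            AtomRecord(serial=start, name="C1", element="C", residue_index=1,
                       residue_name="PRB", segment=Segment.LIGAND,
                       coord=rc, charge=0.0),
            AtomRecord(serial=start + 1, name="O1", element="O",
                       residue_index=1, residue_name="PRB",
                       segment=Segment.LIGAND, coord=ro, charge=0.0),
        ]

    if kind == "single_charge":
        src = [AtomRecord(serial=1, name="NA", element="Na", residue_index=1,
                          residue_name="NA+", segment=Segment.ION,
                          coord=np.zeros(3), charge=1.0)]
        atoms = src + _probe_atoms(2, np.array([3.0, 0, 0]),
                                   np.array([4.0, 0, 0]))
        analytic = COULOMB_K_V_ANG * (1 / 3 - 1 / 4) / 1.0 \
            * V_PER_ANG_TO_MV_PER_CM
        system = ChargedSystem(atoms=atoms)
        return system, ProbeBond(1, 2), analytic

    if kind == "dipole_pair":
        src = [
            AtomRecord(serial=1, name="P", element="Na", residue_index=1,
                       residue_name="NA+", segment=Segment.ION,
                       coord=np.array([0.0, 0, 1.0]), charge=1.0),
            AtomRecord(serial=2, name="M", element="Cl", residue_index=2,
                       residue_name="CL-", segment=Segment.ION,
                       coord=np.array([0.0, 0, -1.0]), charge=-1.0),
        ]
        atoms = src + _probe_atoms(3, np.array([2.0, 0, 0]),
                                   np.array([3.0, 0, 0]))
        system = ChargedSystem(atoms=atoms)
        return system, ProbeBond(2, 3), analytic_zero()

    if kind == "capacitor":
        half_width = kwargs.get("half_width", 25.0)
        spacing = kwargs.get("spacing", 0.15)
        z_plate = kwargs.get("z_plate", 0.3)
        q_site = kwargs.get("q_site", 1.0e-4)
        xs = np.arange(-half_width, half_width + spacing / 2, spacing)
        gx, gy = np.meshgrid(xs, xs)
        n_site = gx.size
        atoms: list[AtomRecord] = []
        serial = 1
        for z, q in ((-z_plate, q_site), (z_plate, -q_site)):
            for x, y in zip(gx.ravel(), gy.ravel()):
                atoms.append(AtomRecord(
                    serial=serial, name="Q", element="X" if False else "C",
                    residue_index=1 if q > 0 else 2, residue_name="SHT",
                    segment=Segment.ION, coord=np.array([x, y, z]), charge=q))
                serial += 1
        # probe spans the midplane along z; field points +z (from + to - plate)
        z_probe = z_plate / 2.0
        atoms += _probe_atoms(serial, np.array([0.0, 0, -z_probe]),
                              np.array([0.0, 0, z_probe]))
        sigma = q_site / spacing ** 2
        analytic = 4 * np.pi * COULOMB_K_V_ANG * sigma * V_PER_ANG_TO_MV_PER_CM
        system = ChargedSystem(atoms=atoms)
        return system, ProbeBond(2 * n_site, 2 * n_site + 1), float(analytic)

    raise ValueError(f"unknown benchmark kind {kind!r}")


def analytic_zero() -> float:
    return 0.0


def make_probe_system(spec: ToySpec, ring: bool = True,
                      offset_from_chain: float = 8.0):
    """Convenience: a toy polypeptide with a probe ligand placed beside it.

    Returns ``(system, probe, exclusion_indices)`` with ligand atoms appended
    after the protein atoms (indices remapped accordingly).
    """
    protein = make_toy_polypeptide(spec)
    center = protein.coords.mean(axis=0)
    lig, probe, excl = make_probe_ligand(
        center + np.array([0.0, -offset_from_chain, 0.0]),
        np.array([0.0, -1.0, 0.0]), ring=ring)
    n = protein.n_atoms
    system = merge_systems(protein, lig)
    probe = ProbeBond(probe.c_index + n, probe.o_index + n)
    excl = [i + n for i in excl]
    return system, probe, excl
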