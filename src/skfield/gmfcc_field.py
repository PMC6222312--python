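"""Fragment-assembled electrostatic potentials and probe-bond fields.

The assembled potential at a point is the signed sum over the fragment
scheme,

    V = sum(capped fragments) - sum(concaps)
        + sum over contact pairs of (pair - single_i - single_j),

each term evaluated by the selected ESP backend with the fragment embedded
in the point charges of the rest of the protein (and ligand).  With the
additive point-charge surrogate backend this telescopes exactly to the
whole-system Coulomb potential — the identity every test here exploits.

The probe-bond field combines three separately reported components:

* the assembled (fragment/QM) potential drop of the **protein**, evaluated at
  points slightly off the C and O centers toward the bond midpoint;
* the classical time-average field of the **ligand** (its probe carbonyl and
  fused ring excluded);
* the classical time-average field of the **solvent** (waters and ions).

A single representative frame carries the fragment calculation: the frame
whose classical total field lies closest to the trajectory's time average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classical_field import (ExclusionSet, FieldRecord, FieldSeries,
                              field_series)
from .constants import V_PER_ANG_TO_MV_PER_CM
from .esp_backends import ESPRequest, ESPResult
from .gmfcc_fragmentation import Fragment, FragmentScheme, embedding_charges
from .structures import ChargedSystem, ProbeBond, Segment, Trajectory

__all__ = [
    "AssembledESP",
    "GMFCCFieldResult",
    "assemble_esp",
    "gmfcc_bond_field",
    "select_representative_frame",
]


@dataclass
class AssembledESP:
    """Assembled per-point potentials plus the signed per-fragment ledger."""

    points: np.ndarray
    potentials: np.ndarray  # volts
    ledger: list[tuple[str, int, np.ndarray]]  # (fragment_id, sign, values)

    def __post_init__(self) -> None:
        total = np.zeros_like(self.potentials)
        for _fid, sign, vals in self.ledger:
            total = total + sign * vals
        scale = np.maximum(np.abs(self.potentials), 1.0)
        if np.any(np.abs(total - self.potentials) > 1e-12 * scale):
            raise ValueError("ledger does not sum to the assembled total")

    def gconcap_corrections(self) -> dict[str, np.ndarray]:
        """Net two-body correction per contact pair (pair − singles)."""
        out: dict[str, np.ndarray] = {}
        for fid, sign, vals in self.ledger:
            if not fid.startswith("gconcap:"):
                continue
            pair_id = fid.split("|")[0]
            out[pair_id] = out.get(pair_id, 0.0) + sign * vals
        return out


def _request_for(fragment: Fragment, scheme: FragmentScheme,
                 system: ChargedSystem, points: np.ndarray,
                 include_solvent_background: bool,
                 frame: np.ndarray | None) -> ESPRequest:
    coords = system.coords if frame is None else np.asarray(frame)
    members = list(fragment.member_atoms)
    bg_xyz, bg_q = embedding_charges(scheme, fragment, system,
                                     include_solvent=include_solvent_background)
    link_pos = np.array([la.position for la in fragment.link_atoms],
                        dtype=float).reshape(-1, 3)
    return ESPRequest(
        elements=tuple(system.atoms[i].element for i in members),
        coords=coords[members],
        charges=system.charges[members],
        link_positions=link_pos,
        net_charge=fragment.charge,
        background_coords=bg_xyz,
        background_charges=bg_q,
        points=np.asarray(points, dtype=float),
        eps_eff=system.eps_eff,
        fragment_id=fragment.fragment_id,
    )


def assemble_esp(scheme: FragmentScheme,
                 backend: Callable[[ESPRequest], ESPResult],
                 points: Sequence[np.ndarray] | np.ndarray,
                 system: ChargedSystem,
                 include_solvent_background: bool = False,
                 frame: np.ndarray | None = None) -> AssembledESP:
    """Signed fragment assembly of the ESP at one or more points.

    Any backend failure aborts with the offending fragment's id.  The result
    carries a full audit ledger of (fragment id, sign, per-point values).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ledger: list[tuple[str, int, np.ndarray]] = []
    total = np.zeros(len(points))
    for frag in scheme.fragments:
        req = _request_for(frag, scheme, system, points,
                           include_solvent_background, frame)
        try:
            res = backend(req)
        except Exception as exc:
            raise RuntimeError(
                f"ESP backend failed on fragment {frag.fragment_id}: {exc}"
            ) from exc
        vals = np.asarray(res.potentials, dtype=float)
        ledger.append((frag.fragment_id, frag.sign, vals))
        total = total + frag.sign * vals
    return AssembledESP(points=points, potentials=total, ledger=ledger)


@dataclass
class GMFCCFieldResult:
    """Total probe-bond field with its three components (MV/cm)."""

    protein_qm: float
    ligand_classical: float
    solvent_classical: float
    selected_frame: int
    assembled: AssembledESP
    classical_series: FieldSeries

    @property
    def total(self) -> float:
        return self.protein_qm + self.ligand_classical + self.solvent_classical

    @property
    def components(self) -> dict[str, float]:
        return {
            "protein_qm": self.protein_qm,
            "ligand_classical": self.ligand_classical,
            "solvent_classical": self.solvent_classical,
            "total": self.total,
        }


def select_representative_frame(series: FieldSeries | Sequence[float]) -> int:
    """Index of the frame whose field lies closest to the time average.

    Ties break toward the earliest frame.
    """
    fields = (series.fields if isinstance(series, FieldSeries)
              else np.asarray(list(series), dtype=float))
    if fields.size == 0:
        raise ValueError("empty field series")
    dev = np.abs(fields - fields.mean())
    return int(np.argmin(dev))  # argmin returns the first minimum


def gmfcc_bond_field(system: ChargedSystem,
                     traj: Trajectory,
                     scheme: FragmentScheme,
                     backend: Callable[[ESPRequest], ESPResult],
                     probe: ProbeBond,
                     excl: ExclusionSet,
                     offset: float = 0.1,
                     include_solvent_background: bool = False
                     ) -> GMFCCFieldResult:
    """Probe-bond field from the fragment assembly with classical amendments.

    The classical total-field series over ``traj`` (with the supplied
    exclusions) selects the representative frame; the assembled protein
    potential is evaluated on that frame at the off-center points, while the
    ligand and solvent contributions are classical time averages over all
    frames with the same exclusions.
    """
    if traj.topology is not system and traj.topology.n_atoms != system.n_atoms:
        raise ValueError("trajectory topology does not match the system")
    # classical total series -> representative snapshot
    series = field_series(traj, probe, excl, offset=offset)
    sel = select_representative_frame(series)
    frame = traj.frames[sel]

    # classical time-average amendments, per segment
    lig_idx = np.setdiff1d(system.segment_atoms(Segment.LIGAND),
                           np.asarray(sorted(excl.indices), dtype=int))
    solv_idx = np.concatenate([system.segment_atoms(Segment.SOLVENT),
                               system.segment_atoms(Segment.ION)])
    lig_field = (field_series(traj, probe, excl, offset=offset,
                              subset=lig_idx, group="ligand").mean
                 if lig_idx.size else 0.0)
    solv_field = (field_series(traj, probe, excl, offset=offset,
                               subset=solv_idx, group="solvent").mean
                  if solv_idx.size else 0.0)

    # assembled protein potential at off-center points on the selected frame
    r_c, r_o, length, unit = probe.geometry(frame)
    if offset < 0 or offset >= length / 2:
        raise ValueError(f"offset must lie in [0, {length / 2:.3f}) Å")
    points = np.vstack([r_c + offset * unit, r_o - offset * unit])
    assembled = assemble_esp(scheme, backend, points, system,
                             include_solvent_background=include_solvent_background,
                             frame=frame)
    phi_c, phi_o = assembled.potentials
    protein_qm = (phi_c - phi_o) / length * V_PER_ANG_TO_MV_PER_CM

    return GMFCCFieldResult(
        protein_qm=float(protein_qm),
        ligand_classical=float(lig_field),
        solvent_classical=float(solv_field),
        selected_frame=sel,
        assembled=assembled,
        classical_series=series,
    )
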