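"""Point-charge electrostatics: potentials, probe-bond fields, decompositions
and hydrogen-bond length analysis.

The electrostatic potential at a point r is the unscreened Coulomb sum

    phi(r) = (1/eps_eff) * k * sum_j q_j / |r - r_j|     [volts]

over every atom not excluded (the probe carbonyl and its fused ring are
always removed from the sum: evaluating the field of a group at points inside
that same group gives non-physical values).  k = 14.399645 V·Å/e.

The mean field along the C=O probe bond is the potential drop per length,

    F = (phi_C - phi_O) / |r_CO| * 100    [MV/cm]

evaluated at points optionally displaced off the atomic centers toward the
bond midpoint.  The sign is literal: negative fields point from O to C.
No cutoff and no periodic imaging are applied — the sum runs over all atoms
present in the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import COULOMB_K_V_ANG, V_PER_ANG_TO_MV_PER_CM
from .structures import ChargedSystem, ProbeBond, Segment, Trajectory

__all__ = [
    "ExclusionSet",
    "FieldRecord",
    "FieldSeries",
    "HBondResult",
    "esp_at_point",
    "bond_field",
    "field_series",
    "decompose_field",
    "hbond_series",
]

_SINGULAR_TOL = 1e-6  # Å


@dataclass(frozen=True)
class ExclusionSet:
    """Atoms removed from every ESP sum (probe C=O plus its ring, and
    optionally whole segments)."""

    indices: frozenset[int] = frozenset()

    @classmethod
    def from_probe(cls, probe: ProbeBond,
                   ring_indices: Iterable[int] = (),
                   system: ChargedSystem | None = None,
                   segments: Iterable[Segment] = ()) -> "ExclusionSet":
        idx = {probe.c_index, probe.o_index, *ring_indices}
        for seg in segments:
            if system is None:
                raise ValueError("segment exclusion requires the system")
            idx.update(system.segment_atoms(Segment(seg)).tolist())
        return cls(indices=frozenset(idx))

    def validate(self, system: ChargedSystem) -> None:
        bad = [i for i in self.indices if not 0 <= i < system.n_atoms]
        if bad:
            raise ValueError(f"excluded atoms not in system: {sorted(bad)}")

    def included(self, system: ChargedSystem) -> np.ndarray:
        self.validate(system)
        mask = np.ones(system.n_atoms, dtype=bool)
        mask[list(self.indices)] = False
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class FieldRecord:
    """ESP at the two probe-side points and the projected field.

    ``field`` (MV/cm) always equals ``(phi_c - phi_o) / length * 100`` with
    ``length`` in Å.
    """

    phi_c: float
    phi_o: float
    length: float
    field: float
    frame_index: int = 0
    group: str = "total"

    def __post_init__(self) -> None:
        expect = (self.phi_c - self.phi_o) / self.length \
            * V_PER_ANG_TO_MV_PER_CM
        scale = max(abs(expect), 1.0)
        if abs(self.field - expect) > 1e-9 * scale:
            raise ValueError("inconsistent FieldRecord: field does not match "
                             "(phi_c - phi_o)/length")

    @classmethod
    def build(cls, phi_c: float, phi_o: float, length: float,
              frame_index: int = 0, group: str = "total") -> "FieldRecord":
        return cls(phi_c=phi_c, phi_o=phi_o, length=length,
                   field=(phi_c - phi_o) / length * V_PER_ANG_TO_MV_PER_CM,
                   frame_index=frame_index, group=group)


class SingularPointError(ValueError):
    def __init__(self, local_index: int, distance: float):
        self.local_index = local_index
        self.distance = distance
        super().__init__(f"evaluation point coincides with a source atom "
                         f"(distance {distance:.2e} Å)")


def _coulomb_sum(coords: np.ndarray, charges: np.ndarray,
                 point: np.ndarray, eps_eff: float) -> float:
    if coords.shape[0] == 0:
        return 0.0
    d = np.linalg.norm(coords - point, axis=1)
    imin = int(np.argmin(d))
    if d[imin] <= _SINGULAR_TOL:
        raise SingularPointError(imin, float(d[imin]))
    return float(COULOMB_K_V_ANG / eps_eff * np.sum(charges / d))


def esp_at_point(system: ChargedSystem, point: np.ndarray,
                 excl: ExclusionSet = ExclusionSet(),
                 coords: np.ndarray | None = None,
                 subset: np.ndarray | None = None) -> float:
    """Electrostatic potential (V) at ``point`` from all included atoms.

    ``coords`` substitutes a trajectory frame for the topology coordinates;
    ``subset`` restricts the source atoms (it is intersected with the
    non-excluded set), which is how per-group decompositions are computed.
    """
    point = np.asarray(point, dtype=float)
    idx = excl.included(system)
    if subset is not None:
        idx = np.intersect1d(idx, np.asarray(subset, dtype=int))
    xyz = (system.coords if coords is None else np.asarray(coords))[idx]
    q = system.charges[idx]
    try:
        return _coulomb_sum(xyz, q, point, system.eps_eff)
    except SingularPointError as exc:
        serial = system.atoms[int(idx[exc.local_index])].serial
        raise ValueError(f"evaluation point coincides with atom {serial} "
                         f"(distance {exc.distance:.2e} Å)") from None


def bond_field(system: ChargedSystem, probe: ProbeBond,
               excl: ExclusionSet = ExclusionSet(),
               offset: float = 0.0,
               coords: np.ndarray | None = None,
               subset: np.ndarray | None = None,
               frame_index: int = 0,
               group: str = "total") -> FieldRecord:
    """Mean field along the probe bond, in MV/cm.

    The evaluation points are the C and O centers, each moved ``offset`` Å
    toward the bond midpoint; the drop is divided by the full bond length.
    """
    frame = system.coords if coords is None else np.asarray(coords)
    r_c, r_o, length, unit = probe.geometry(frame)
    if offset < 0 or offset >= length / 2:
        raise ValueError(f"offset must lie in [0, {length / 2:.3f}) Å")
    p_c = r_c + offset * unit
    p_o = r_o - offset * unit
    phi_c = esp_at_point(system, p_c, excl, coords=frame, subset=subset)
    phi_o = esp_at_point(system, p_o, excl, coords=frame, subset=subset)
    return FieldRecord.build(phi_c, phi_o, length,
                             frame_index=frame_index, group=group)


@dataclass
class FieldSeries:
    """Per-frame field records and their unweighted arithmetic mean."""

    records: list[FieldRecord]

    @property
    def fields(self) -> np.ndarray:
        return np.array([r.field for r in self.records], dtype=float)

    @property
    def mean(self) -> float:
        return float(self.fields.mean())

    @property
    def std_error(self) -> float:
        f = self.fields
        if f.size < 2:
            return 0.0
        return float(f.std(ddof=1) / np.sqrt(f.size))


def field_series(traj: Trajectory, probe: ProbeBond,
                 excl: ExclusionSet = ExclusionSet(),
                 offset: float = 0.0,
                 subset: np.ndarray | None = None,
                 group: str = "total") -> FieldSeries:
    """Per-frame probe-bond fields over a trajectory plus their time average
    (a plain mean over saved frames, no timestep weighting)."""
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    records = [
        bond_field(traj.topology, probe, excl, offset=offset, coords=f,
                   subset=subset, frame_index=t, group=group)
        for t, f in enumerate(traj.frames)
    ]
    return FieldSeries(records=records)


def decompose_field(system: ChargedSystem, probe: ProbeBond,
                    excl: ExclusionSet,
                    groups: Mapping[str, Iterable[int]],
                    offset: float = 0.0,
                    coords: np.ndarray | None = None,
                    frame_index: int = 0) -> dict[str, FieldRecord]:
    """Per-group probe-bond fields for a partition of the included atoms.

    ``groups`` maps labels to atom-index collections that must partition the
    non-excluded atoms exactly.  By linearity the group fields sum to the
    total field; a ``"total"`` record is included in the returned map.
    """
    included = set(excl.included(system).tolist())
    seen: set[int] = set()
    for label, idx in groups.items():
        s = set(int(i) for i in idx)
        if s & seen:
            raise ValueError(f"group {label!r} overlaps another group")
        if not s <= included:
            raise ValueError(f"group {label!r} contains excluded or unknown "
                             f"atoms")
        seen |= s
    if seen != included:
        missing = sorted(included - seen)
        raise ValueError(f"groups do not cover included atoms; missing "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    out: dict[str, FieldRecord] = {}
    for label, idx in groups.items():
        out[label] = bond_field(system, probe, excl, offset=offset,
                                coords=coords,
                                subset=np.asarray(list(idx), dtype=int),
                                frame_index=frame_index, group=label)
    out["total"] = bond_field(system, probe, excl, offset=offset,
                              coords=coords, frame_index=frame_index,
                              group="total")
    return out


@dataclass
class HBondResult:
    """Distance series and occupancy for one donor–acceptor heavy-atom pair."""

    pair: tuple[int, int]
    distances: np.ndarray
    cutoff: float
    bin_width: float

    @property
    def occupancy(self) -> float:
        """Fraction of frames with distance <= cutoff (bond intact)."""
        return float(np.mean(self.distances <= self.cutoff))

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts, bin_edges) over bins of ``bin_width`` Å spanning the
        observed range."""
        lo = np.floor(self.distances.min() / self.bin_width) * self.bin_width
        hi = np.ceil(self.distances.max() / self.bin_width) * self.bin_width
        nbins = max(1, int(round((hi - lo) / self.bin_width)))
        return np.histogram(self.distances, bins=nbins, range=(lo, hi))


def hbond_series(traj: Trajectory,
                 pairs: Sequence[tuple[int, int]],
                 cutoff: float = 3.5,
                 bin_width: float = 0.1) -> list[HBondResult]:
    """Heavy-atom H-bond distance series over a trajectory.

    A hydrogen bond is counted as broken in frames where the donor–acceptor
    distance exceeds ``cutoff`` (3.5 Å by default).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    for a, b in pairs:
        if a == b:
            raise ValueError(f"pair ({a}, {b}): atoms must be distinct")
        if not (0 <= a < traj.topology.n_atoms
                and 0 <= b < traj.topology.n_atoms):
            raise ValueError(f"pair ({a}, {b}): atom index out of range")
    stack = np.stack(traj.frames)  # (T, n, 3)
    out = []
    for a, b in pairs:
        d = np.linalg.norm(stack[:, a, :] - stack[:, b, :], axis=1)
        out.append(HBondResult(pair=(a, b), distances=d, cutoff=cutoff,
                               bin_width=bin_width))
    return out
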