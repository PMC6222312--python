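"""Charged structures, probe bonds and trajectories.

This module owns the in-memory containers every other stage consumes: a
:class:`ChargedSystem` (atoms with coordinates in Å and partial charges in e,
partitioned into residues), a :class:`ProbeBond` (the carbonyl C/O pair whose
bond-projected field is the quantity of interest) and a :class:`Trajectory`
(ordered coordinate frames over one topology).

Supported interchange formats are deliberately narrow:

* **PQR** — whitespace-separated ATOM/HETATM records carrying charge and
  radius after the coordinates.  This is the canonical charged-structure
  format; it round-trips coordinates and charges to 1e-6.
* **PDB** — fixed-width ATOM/HETATM records; charges are zero until
  :func:`assign_charges` is applied from a charge table.
* **multi-model PDB** — MODEL/ENDMDL blocks, one frame per model, used as the
  plain-text trajectory format.

Residues are keyed by ``(segment, chain_id, residue_index)``.  Segment
classification (protein / ligand / solvent / ion) follows residue names and is
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "AtomRecord",
    "ChargedSystem",
    "ProbeBond",
    "Trajectory",
    "ParseError",
    "read_structure",
    "write_structure",
    "assign_charges",
    "read_trajectory",
    "write_trajectory",
    "residue_min_distance",
    "merge_systems",
    "classify_segment",
]


class Segment(str, Enum):
    """Coarse classification of an atom's parent molecule."""

    PROTEIN = "protein"
    LIGAND = "ligand"
    SOLVENT = "solvent"
    ION = "ion"


#: Residue names classified as water/solvent.
WATER_RESIDUES = {"HOH", "WAT", "TIP3", "SOL"}

#: Residue names classified as monoatomic ions.
ION_RESIDUES = {"NA+", "CL-", "NA", "CL", "K", "K+", "MG", "MG2", "ZN", "CA2"}

#: The twenty standard amino acids plus common protonation variants.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX",
}


def classify_segment(residue_name: str,
                     overrides: Mapping[str, Segment] | None = None) -> Segment:
    """Classify a residue name into a :class:`Segment`.

    Waters -> solvent, known ions -> ion, standard amino acids -> protein,
    everything else -> ligand.  ``overrides`` maps residue names to segments
    and wins over the built-in tables.
    """
    name = residue_name.strip().upper()
    if overrides and name in overrides:
        return Segment(overrides[name])
    if name in WATER_RESIDUES:
        return Segment.SOLVENT
    if name in ION_RESIDUES:
        return Segment.ION
    if name in AMINO_ACIDS:
        return Segment.PROTEIN
    return Segment.LIGAND


class ParseError(ValueError):
    """A structure file failed to parse; the message names the line."""


@dataclass
class AtomRecord:
    """One atom: identity, residue membership, coordinates (Å), charge (e)."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    segment: Segment
    coord: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom {self.serial}: coord must be a 3-vector")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")
        if self.residue_index < 1:
            raise ValueError(f"atom {self.serial}: residue_index must be >= 1")


ResidueKey = tuple[Segment, str, int]


@dataclass
class ChargedSystem:
    """An ordered collection of charged atoms grouped into residues.

    ``eps_eff`` is the effective dielectric constant dividing every
    electrostatic potential computed over this system (1.0 by default, the
    value appropriate when solvent is represented explicitly).
    """

    atoms: list[AtomRecord]
    eps_eff: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_eff <= 0:
            raise ValueError("eps_eff must be positive")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            dup = sorted({s for s in serials if serials.count(s) > 1})
            raise ValueError(f"duplicate atom serial(s): {dup}")

    # -- array views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        """(n_atoms,) partial charges, e."""
        return np.array([a.charge for a in self.atoms], dtype=float)

    # -- residue bookkeeping ----------------------------------------------

    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys in first-appearance order."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault((a.segment, a.chain_id, a.residue_index), None)
        return list(seen)

    def residue_atoms(self, key: ResidueKey) -> np.ndarray:
        """Indices (into ``atoms``) of one residue group."""
        seg, chain, idx = key
        out = [i for i, a in enumerate(self.atoms)
               if a.segment == seg and a.chain_id == chain
               and a.residue_index == idx]
        if not out:
            raise KeyError(f"no atoms in residue {key}")
        return np.asarray(out, dtype=int)

    def segment_atoms(self, segment: Segment) -> np.ndarray:
        segment = Segment(segment)
        return np.asarray(
            [i for i, a in enumerate(self.atoms) if a.segment == segment],
            dtype=int)

    def protein_runs(self) -> list[list[ResidueKey]]:
        """Contiguous protein chains as runs of residue keys.

        A run breaks on a chain-id change or a residue-number gap; peptide
        fragmentation must never cut across such a break.
        """
        keys = [k for k in self.residue_keys() if k[0] == Segment.PROTEIN]
        runs: list[list[ResidueKey]] = []
        for k in keys:
            if runs and runs[-1][-1][1] == k[1] and runs[-1][-1][2] + 1 == k[2]:
                runs[-1].append(k)
            else:
                runs.append([k])
        return runs

    def atom_index(self, residue_index: int, atom_name: str,
                   segment: Segment = Segment.PROTEIN,
                   chain_id: str | None = None) -> int:
        """Locate a single atom by residue number and atom name."""
        for i, a in enumerate(self.atoms):
            if (a.segment == segment and a.residue_index == residue_index
                    and a.name == atom_name
                    and (chain_id is None or a.chain_id == chain_id)):
                return i
        raise KeyError(f"atom {atom_name} of {segment.value} residue "
                       f"{residue_index} not found")


@dataclass(frozen=True)
class ProbeBond:
    """The C=O probe bond: indices of the carbonyl C and O atoms."""

    c_index: int
    o_index: int

    def __post_init__(self) -> None:
        if self.c_index == self.o_index:
            raise ValueError("probe C and O must be distinct atoms")

    def geometry(self, coords: np.ndarray):
        """Return (r_C, r_O, length, unit C->O) for one coordinate frame."""
        r_c = np.asarray(coords[self.c_index], dtype=float)
        r_o = np.asarray(coords[self.o_index], dtype=float)
        vec = r_o - r_c
        length = float(np.linalg.norm(vec))
        if length <= 0:
            raise ValueError("zero-length probe bond")
        return r_c, r_o, length, vec / length


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology."""

    topology: ChargedSystem
    frames: list[np.ndarray]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {i}: expected {n} atoms, got {f.shape[0]}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_pqr_line(line: str, lineno: int,
                    overrides: Mapping[str, Segment] | None) -> AtomRecord:
    parts = line.split()
    # recname serial name resname [chain] resid x y z charge radius
    if len(parts) == 11:
        _, serial, name, resname, chain, resid = parts[:6]
        rest = parts[6:]
    elif len(parts) == 10:
        _, serial, name, resname, resid = parts[:5]
        chain = "A"
        rest = parts[5:]
    else:
        raise ParseError(f"line {lineno}: malformed PQR record "
                         f"({len(parts)} fields): {line.rstrip()}")
    try:
        x, y, z, charge, radius = (float(v) for v in rest)
        serial_i, resid_i = int(serial), int(resid)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    return AtomRecord(
        serial=serial_i, name=name, element=_element_from_name(name),
        residue_index=resid_i, residue_name=resname,
        segment=classify_segment(resname, overrides),
        coord=np.array([x, y, z]), charge=charge, radius=radius,
        chain_id=chain)


def _parse_pdb_line(line: str, lineno: int,
                    overrides: Mapping[str, Segment] | None) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed PDB record: "
                         f"{line.rstrip()!r} ({exc})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    return AtomRecord(
        serial=serial, name=name,
        element=element or _element_from_name(name),
        residue_index=resid, residue_name=resname,
        segment=classify_segment(resname, overrides),
        coord=np.array([x, y, z]), chain_id=chain)


def _element_from_name(name: str) -> str:
    """Best-effort element from an atom name (first alphabetic character,
    honouring two-letter names like CL/NA when they match a known ion)."""
    stripped = name.strip().upper()
    if stripped in {"CL", "NA", "MG", "ZN", "BR", "FE"}:
        return stripped.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch
    return "X"


def read_structure(path: str | Path, dialect: str = "pqr",
                   segment_overrides: Mapping[str, Segment] | None = None,
                   altloc: str = "A") -> ChargedSystem:
    """Read a PQR or PDB file into a :class:`ChargedSystem`.

    Atoms appear in file order.  For the ``pdb`` dialect charges are zero
    until :func:`assign_charges` is applied.  Alternate locations other than
    blank or ``altloc`` are dropped (and logged).
    """
    path = Path(path)
    if dialect not in ("pdb", "pqr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    atoms: list[AtomRecord] = []
    n_alt_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if dialect == "pdb":
                alt = line[16].strip() if len(line) > 16 else ""
                if alt and alt != altloc:
                    n_alt_dropped += 1
                    continue
                atoms.append(_parse_pdb_line(line, lineno, segment_overrides))
            else:
                atoms.append(_parse_pqr_line(line, lineno, segment_overrides))
    if n_alt_dropped:
        logger.info("dropped %d alternate-location atoms (kept altloc %r)",
                    n_alt_dropped, altloc)
    return ChargedSystem(atoms=atoms)


def write_structure(system: ChargedSystem, path: str | Path,
                    dialect: str = "pqr") -> None:
    """Write a system as PQR (coordinates/charges to 1e-6) or PDB (fixed
    width, coordinates to 1e-3)."""
    path = Path(path)
    lines: list[str] = []
    for a in system.atoms:
        if dialect == "pqr":
            lines.append(
                f"ATOM {a.serial:6d} {a.name:<4s} {a.residue_name:<4s} "
                f"{a.chain_id:1s} {a.residue_index:4d} "
                f"{a.coord[0]:12.6f} {a.coord[1]:12.6f} {a.coord[2]:12.6f} "
                f"{a.charge:10.6f} {a.radius:8.4f}")
        elif dialect == "pdb":
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4s}{a.residue_name:<4s}"
                f"{a.chain_id:1s}{a.residue_index:4d}    "
                f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def assign_charges(system: ChargedSystem,
                   table: Mapping[tuple[str, str], float],
                   default: float | None = None) -> ChargedSystem:
    """Return a copy of ``system`` with charges taken from a
    ``(residue_name, atom_name) -> charge`` table.

    Solvent and ion atoms keep their existing charges unless the table names
    them.  Protein/ligand atoms without a table entry fall back to
    ``default``; if ``default`` is None the missing pairs are collected and
    reported in one error.
    """
    missing: list[tuple[str, str]] = []
    new_atoms: list[AtomRecord] = []
    for a in system.atoms:
        key = (a.residue_name, a.name)
        if key in table:
            q = table[key]
        elif a.segment in (Segment.SOLVENT, Segment.ION):
            q = a.charge
        elif default is not None:
            q = default
        else:
            missing.append(key)
            continue
        new_atoms.append(replace(a, charge=q, coord=a.coord.copy()))
    if missing:
        raise KeyError("no charge-table entry (and no default) for: "
                       + ", ".join(f"{r}:{n}" for r, n in sorted(set(missing))))
    out = ChargedSystem(atoms=new_atoms, eps_eff=system.eps_eff)
    for key in out.residue_keys():
        idx = out.residue_atoms(key)
        total = float(sum(out.atoms[i].charge for i in idx))
        logger.info("residue %s net charge %+0.4f e", key, total)
    return out


def read_trajectory(path: str | Path, topology: ChargedSystem) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory` over ``topology``.

    Every MODEL block (or the whole file, if there are no MODEL records) must
    contain exactly one ATOM/HETATM record per topology atom, in topology
    order; a mismatch raises an error naming the offending model.
    """
    path = Path(path)
    n_expect = topology.n_atoms
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    model_no = 0
    saw_model = False

    def _close(model: int) -> None:
        if len(current) != n_expect:
            raise ParseError(
                f"model {model}: expected {n_expect} atoms, "
                f"got {len(current)}")
        frames.append(np.asarray(current, dtype=float))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                saw_model = True
                model_no += 1
                current = []
            elif line.startswith("ENDMDL"):
                _close(model_no)
                current = []
            elif line.startswith(("ATOM", "HETATM")):
                try:
                    current.append([float(line[30:38]), float(line[38:46]),
                                    float(line[46:54])])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"line {lineno}: {exc}") from None
    if not saw_model:
        _close(1)
    elif current:
        # MODEL without closing ENDMDL — tolerate, but validate.
        _close(model_no)
    if not frames:
        raise ParseError(f"{path}: no coordinate frames found")
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (coordinates to 1e-3 Å)."""
    path = Path(path)
    lines: list[str] = []
    for m, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for a, xyz in zip(traj.topology.atoms, frame):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4s}{a.residue_name:<4s}"
                f"{a.chain_id:1s}{a.residue_index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry utilities
# ---------------------------------------------------------------------------

def residue_min_distance(system: ChargedSystem, frame: np.ndarray,
                         group_a: ResidueKey | Iterable[int],
                         group_b: ResidueKey | Iterable[int]) -> float:
    """Minimum Euclidean distance (Å) between two disjoint atom groups.

    Groups may be residue keys or explicit index collections.  Symmetric in
    its arguments.
    """
    idx_a = _group_indices(system, group_a)
    idx_b = _group_indices(system, group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("empty residue group")
    if set(idx_a.tolist()) & set(idx_b.tolist()):
        raise ValueError("residue groups must be disjoint")
    frame = np.asarray(frame, dtype=float)
    return float(cdist(frame[idx_a], frame[idx_b]).min())


def _group_indices(system: ChargedSystem, group) -> np.ndarray:
    if isinstance(group, tuple) and len(group) == 3 and isinstance(group[2], int):
        return system.residue_atoms(group)
    return np.asarray(list(group), dtype=int)


def merge_systems(*systems: ChargedSystem, eps_eff: float | None = None
                  ) -> ChargedSystem:
    """Concatenate systems into one, renumbering serials sequentially.

    Returns the merged system; atom order is the concatenation order, so an
    index offset for the k-th input is the total atom count of inputs 0..k-1.
    """
    atoms: list[AtomRecord] = []
    serial = 1
    for sys_ in systems:
        for a in sys_.atoms:
            atoms.append(replace(a, serial=serial, coord=a.coord.copy()))
            serial += 1
    return ChargedSystem(atoms=atoms,
                         eps_eff=eps_eff if eps_eff is not None
                         else systems[0].eps_eff)
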