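"""Generalized molecular-fractionation bookkeeping: capped fragments,
conjugate caps, generalized concaps and embedding charges.

A protein of N contiguous residues is cut at every peptide bond and
reassembled as a signed sum of small capped pieces:

* **capped fragments** (sign +1), one per residue i = 2..N-1: residue i plus
  a cap from each sequence neighbor;
* **conjugate caps / concaps** (sign -1), i = 2..N-2: exactly the pair of
  caps shared by adjacent capped fragments, subtracted to cancel the double
  counting;
* **generalized concaps (gconcaps)**: for every residue pair (i, j) with
  j > i+2 whose minimum interatomic distance is within a threshold λ
  (default 4.0 Å), a two-body correction  pair − single_i − single_j  of
  hydrogen-capped isolated residues (pair sign +1, singles sign −1).  A bound
  ligand can participate as one partner, taken whole.

The cap taken from residue i±1 is the minimal backbone unit adjacent to the
cut — the C=O/Cα piece on the N side of the cut, the N/Cα piece on the C
side — with the Cα turned into a methyl-like terminus by hydrogen link atoms.
Terminal residues 1 and N are absorbed whole into the caps of fragments 2 and
N−1.  This is the minimal recipe for which a concap's atoms coincide
coordinate-for-coordinate with the caps of its two adjacent capped fragments,
which is what makes the signed sum telescope: every protein atom carries a
signed multiplicity of exactly +1 across the scheme.

Dangling bonds created by a cut are saturated by hydrogen link atoms placed
on the cut-bond axis, 1.09 Å from a kept carbon and 1.01 Å from a kept
nitrogen.  Link atoms carry no charge and never appear in embedding
backgrounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .structures import (ChargedSystem, ResidueKey, Segment,
                         residue_min_distance)

logger = logging.getLogger(__name__)

__all__ = [
    "LinkAtom",
    "Fragment",
    "FragmentScheme",
    "fragment_protein",
    "place_link_atom",
    "build_gconcaps",
    "embedding_charges",
]

#: Link-atom bond lengths by kept-atom element, Å.
LINK_BOND_LENGTH = {"C": 1.09, "N": 1.01}

# Atom names forming the two cap pieces of the 5-atom model residue and of
# real backbones.  The C-side cap (donated across the C(i-1)-N(i) cut) keeps
# the carbonyl unit; the N-side cap keeps the amide unit.  Cα appears in
# both; its remaining bonds (to N or C of its own residue, and to the
# side-chain CB) are cut and hydrogen-saturated.
CSIDE_NAMES = ("CA", "C", "O", "HA", "HA2", "HA3")
NSIDE_NAMES = ("N", "CA", "H", "HN")


def place_link_atom(kept_coord: np.ndarray, removed_coord: np.ndarray,
                    kept_element: str) -> np.ndarray:
    """Hydrogen link-atom position on the kept->removed bond axis.

    Placed 1.09 Å from a kept carbon, 1.01 Å from a kept nitrogen.
    """
    kept_coord = np.asarray(kept_coord, dtype=float)
    axis = np.asarray(removed_coord, dtype=float) - kept_coord
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("cut bond has zero length")
    try:
        d = LINK_BOND_LENGTH[kept_element.upper()[0]]
    except KeyError:
        raise ValueError(f"no link-atom bond length for element "
                         f"{kept_element!r}") from None
    return kept_coord + d * axis / norm


@dataclass(frozen=True)
class LinkAtom:
    """A generated capping hydrogen with its cut-bond provenance."""

    position: np.ndarray
    kept_index: int
    removed_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))


@dataclass
class Fragment:
    """One signed term of the fragment assembly.

    ``real_atoms`` are the atoms the fragment represents (weight +1 in the
    assembly); ``cap_atoms`` are copies of neighboring residues' atoms;
    ``link_atoms`` saturate cut bonds.  ``sign`` is the coefficient of this
    fragment's potential in the assembled sum.
    """

    fragment_id: str
    kind: str  # capped_fragment | concap | gconcap_pair | gconcap_single
    center: tuple[ResidueKey, ...]
    real_atoms: tuple[int, ...]
    cap_atoms: tuple[int, ...]
    link_atoms: tuple[LinkAtom, ...]
    sign: int
    charge: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("fragment sign must be +1 or -1")
        if set(self.real_atoms) & set(self.cap_atoms):
            raise ValueError(f"{self.fragment_id}: real and cap atoms overlap")

    @property
    def member_atoms(self) -> tuple[int, ...]:
        """Real plus cap atom indices (link atoms excluded)."""
        return self.real_atoms + self.cap_atoms


@dataclass
class FragmentScheme:
    """The full signed fragment decomposition of one charged system."""

    fragments: list[Fragment]
    lambda_thresh: float
    n_residues: int
    residue_keys: list[ResidueKey]
    gconcap_pairs: list[tuple[ResidueKey, ResidueKey]] = field(
        default_factory=list)
    cap_recipe: str = "minimal-backbone-v1"

    def by_kind(self, kind: str) -> list[Fragment]:
        return [f for f in self.fragments if f.kind == kind]

    def signed_multiplicity(self, n_atoms: int) -> np.ndarray:
        """Signed per-atom multiplicity over capped fragments and concaps.

        Gconcap terms are excluded — their pair/single members cancel by
        construction.  The telescoping invariant is multiplicity exactly 1
        for every protein atom of the covered chain.
        """
        mult = np.zeros(n_atoms, dtype=int)
        for f in self.fragments:
            if f.kind in ("capped_fragment", "concap"):
                for i in f.member_atoms:
                    mult[i] += f.sign
        return mult


def _residue_atom(system: ChargedSystem, key: ResidueKey, name: str) -> int:
    for i in system.residue_atoms(key):
        if system.atoms[i].name == name:
            return int(i)
    raise KeyError(f"residue {key} has no atom {name!r}")


def _cap_cut_links(system: ChargedSystem, key: ResidueKey,
                   kept: set[int]) -> list[LinkAtom]:
    """Link atoms for the Cα of a cap: saturate its bonds to atoms of the
    same residue that are not kept (backbone N or C, and the side chain)."""
    links: list[LinkAtom] = []
    ca = _residue_atom(system, key, "CA")
    if ca not in kept:
        return links
    for name in ("N", "C", "CB"):
        try:
            other = _residue_atom(system, key, name)
        except KeyError:
            continue
        if other in kept:
            continue
        links.append(LinkAtom(
            position=place_link_atom(system.atoms[ca].coord,
                                     system.atoms[other].coord,
                                     system.atoms[ca].element),
            kept_index=ca, removed_index=other))
    return links


def _cside_cap(system: ChargedSystem, key: ResidueKey, terminal: bool):
    """Cap donated by residue ``key`` across its C-terminal peptide bond."""
    res = system.residue_atoms(key)
    if terminal:
        kept = set(int(i) for i in res)
    else:
        kept = {int(i) for i in res if system.atoms[i].name in CSIDE_NAMES}
    return tuple(sorted(kept)), tuple(_cap_cut_links(system, key, kept))


def _nside_cap(system: ChargedSystem, key: ResidueKey, terminal: bool):
    """Cap donated by residue ``key`` across its N-terminal peptide bond."""
    res = system.residue_atoms(key)
    if terminal:
        kept = set(int(i) for i in res)
    else:
        kept = {int(i) for i in res if system.atoms[i].name in NSIDE_NAMES}
    return tuple(sorted(kept)), tuple(_cap_cut_links(system, key, kept))


def _int_charge(system: ChargedSystem, atom_indices: Iterable[int],
                fragment_id: str) -> int:
    total = float(sum(system.atoms[i].charge for i in atom_indices))
    rounded = int(round(total))
    if abs(total - rounded) > 0.01:
        logger.warning("%s: member charge %+.4f e is %.4f e from an integer",
                       fragment_id, total, abs(total - rounded))
    return rounded


def fragment_protein(system: ChargedSystem,
                     lambda_thresh: float = 4.0) -> FragmentScheme:
    """Decompose the protein into capped fragments and conjugate caps.

    Each contiguous chain run of N >= 3 residues yields capped fragments for
    i = 2..N−1 and concaps for i = 2..N−2; terminal residues are absorbed
    into their neighbors' caps.  Runs shorter than 3 residues (after chain
    breaks) raise an error.  Gconcaps are added separately by
    :func:`build_gconcaps`.
    """
    runs = system.protein_runs()
    if not runs:
        raise ValueError("system has no protein residues")
    fragments: list[Fragment] = []
    all_keys: list[ResidueKey] = []
    for run in runs:
        n = len(run)
        if n < 3:
            raise ValueError(
                f"chain run starting at residue {run[0]} has only {n} "
                f"residue(s); fragmentation needs at least 3")
        all_keys.extend(run)
        caps_c = {}  # C-side cap donated by run[k]
        caps_n = {}  # N-side cap donated by run[k]
        for k, key in enumerate(run):
            caps_c[k] = _cside_cap(system, key, terminal=(k == 0))
            caps_n[k] = _nside_cap(system, key, terminal=(k == n - 1))
        chain = run[0][1]
        for k in range(1, n - 1):
            key = run[k]
            real = tuple(int(i) for i in system.residue_atoms(key))
            (cap_prev, links_prev) = caps_c[k - 1]
            (cap_next, links_next) = caps_n[k + 1]
            members = real + cap_prev + cap_next
            fid = f"frag:{chain}:{key[2]}"
            fragments.append(Fragment(
                fragment_id=fid, kind="capped_fragment", center=(key,),
                real_atoms=real, cap_atoms=cap_prev + cap_next,
                link_atoms=links_prev + links_next, sign=+1,
                charge=_int_charge(system, members, fid)))
        for k in range(1, n - 2):
            (cap_i, links_i) = caps_c[k]
            (cap_j, links_j) = caps_n[k + 1]
            fid = f"concap:{chain}:{run[k][2]}-{run[k + 1][2]}"
            members = cap_i + cap_j
            fragments.append(Fragment(
                fragment_id=fid, kind="concap", center=(run[k], run[k + 1]),
                real_atoms=(), cap_atoms=members,
                link_atoms=links_i + links_j, sign=-1,
                charge=_int_charge(system, members, fid)))
    return FragmentScheme(fragments=fragments, lambda_thresh=lambda_thresh,
                          n_residues=len(all_keys), residue_keys=all_keys)


def _capped_single(system: ChargedSystem, key: ResidueKey,
                   run: list[ResidueKey]) -> tuple[tuple[int, ...],
                                                   tuple[LinkAtom, ...]]:
    """A whole residue, hydrogen-capped at both peptide cuts."""
    real = tuple(int(i) for i in system.residue_atoms(key))
    links: list[LinkAtom] = []
    pos = run.index(key)
    if pos > 0:
        n_atom = _residue_atom(system, key, "N")
        c_prev = _residue_atom(system, run[pos - 1], "C")
        links.append(LinkAtom(
            position=place_link_atom(system.atoms[n_atom].coord,
                                     system.atoms[c_prev].coord,
                                     system.atoms[n_atom].element),
            kept_index=n_atom, removed_index=c_prev))
    if pos < len(run) - 1:
        c_atom = _residue_atom(system, key, "C")
        n_next = _residue_atom(system, run[pos + 1], "N")
        links.append(LinkAtom(
            position=place_link_atom(system.atoms[c_atom].coord,
                                     system.atoms[n_next].coord,
                                     system.atoms[c_atom].element),
            kept_index=c_atom, removed_index=n_next))
    return real, tuple(links)


def build_gconcaps(system: ChargedSystem, scheme: FragmentScheme,
                   include_ligand: bool = True,
                   lambda_thresh: float | None = None,
                   heavy_only: bool = False,
                   frame: np.ndarray | None = None) -> FragmentScheme:
    """Add generalized-concap two-body corrections to a scheme.

    For every residue pair (i, j) with j > i+2 within one chain run (and
    every cross-run pair) whose minimum interatomic distance is <= λ, a
    gconcap pair (sign +1) and the two hydrogen-capped singles (sign −1) are
    appended.  With ``include_ligand`` the system's ligand atoms, taken
    whole, may be one partner.  λ distances use all atoms by default
    (``heavy_only`` restricts to non-hydrogens).  Returns ``scheme``
    (modified in place) for chaining.
    """
    lam = scheme.lambda_thresh if lambda_thresh is None else lambda_thresh
    coords = system.coords if frame is None else np.asarray(frame)
    runs = system.protein_runs()
    flat: list[tuple[ResidueKey, list[ResidueKey], int]] = []
    for run in runs:
        for pos, key in enumerate(run):
            flat.append((key, run, pos))

    def _atom_subset(key: ResidueKey) -> np.ndarray:
        idx = system.residue_atoms(key)
        if heavy_only:
            idx = np.asarray([i for i in idx
                              if system.atoms[i].element.upper() != "H"],
                             dtype=int)
        return idx

    singles_cache: dict[ResidueKey, tuple] = {}

    def _single(key: ResidueKey, run: list[ResidueKey]):
        if key not in singles_cache:
            singles_cache[key] = _capped_single(system, key, run)
        return singles_cache[key]

    new: list[Fragment] = []
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    for a in range(len(flat)):
        key_i, run_i, pos_i = flat[a]
        for b in range(a + 1, len(flat)):
            key_j, run_j, pos_j = flat[b]
            if run_i is run_j and pos_j <= pos_i + 2:
                continue  # sequence neighbors handled by concaps
            dmin = residue_min_distance(system, coords,
                                        _atom_subset(key_i),
                                        _atom_subset(key_j))
            if dmin > lam:
                continue
            pairs.append((key_i, key_j))
            real_i, links_i = _single(key_i, run_i)
            real_j, links_j = _single(key_j, run_j)
            pid = f"gconcap:{key_i[1]}{key_i[2]}-{key_j[1]}{key_j[2]}"
            new.append(Fragment(
                fragment_id=pid, kind="gconcap_pair",
                center=(key_i, key_j), real_atoms=real_i + real_j,
                cap_atoms=(), link_atoms=links_i + links_j, sign=+1,
                charge=_int_charge(system, real_i + real_j, pid)))
            for key, real, links in ((key_i, real_i, links_i),
                                     (key_j, real_j, links_j)):
                sid = f"{pid}|single:{key[1]}{key[2]}"
                new.append(Fragment(
                    fragment_id=sid, kind="gconcap_single", center=(key,),
                    real_atoms=real, cap_atoms=(), link_atoms=links, sign=-1,
                    charge=_int_charge(system, real, sid)))

    lig_idx = system.segment_atoms(Segment.LIGAND)
    if include_ligand and lig_idx.size:
        lig_sub = lig_idx
        if heavy_only:
            lig_sub = np.asarray([i for i in lig_idx
                                  if system.atoms[i].element.upper() != "H"],
                                 dtype=int)
        lig_key = (Segment.LIGAND, system.atoms[lig_idx[0]].chain_id,
                   system.atoms[lig_idx[0]].residue_index)
        lig_real = tuple(int(i) for i in lig_idx)
        for key_i, run_i, _pos in flat:
            dmin = residue_min_distance(system, coords,
                                        _atom_subset(key_i), lig_sub)
            if dmin > lam:
                continue
            pairs.append((key_i, lig_key))
            real_i, links_i = _single(key_i, run_i)
            pid = f"gconcap:{key_i[1]}{key_i[2]}-LIG"
            new.append(Fragment(
                fragment_id=pid, kind="gconcap_pair",
                center=(key_i, lig_key), real_atoms=real_i + lig_real,
                cap_atoms=(), link_atoms=links_i, sign=+1,
                charge=_int_charge(system, real_i + lig_real, pid)))
            new.append(Fragment(
                fragment_id=f"{pid}|single:{key_i[1]}{key_i[2]}",
                kind="gconcap_single", center=(key_i,), real_atoms=real_i,
                cap_atoms=(), link_atoms=links_i, sign=-1,
                charge=_int_charge(system, real_i, pid)))
            new.append(Fragment(
                fragment_id=f"{pid}|single:LIG", kind="gconcap_single",
                center=(lig_key,), real_atoms=lig_real, cap_atoms=(),
                link_atoms=(), sign=-1,
                charge=_int_charge(system, lig_real, pid)))

    scheme.fragments = [f for f in scheme.fragments
                        if not f.kind.startswith("gconcap")] + new
    scheme.gconcap_pairs = pairs
    return scheme


def embedding_charges(scheme: FragmentScheme, fragment: Fragment,
                      system: ChargedSystem,
                      include_solvent: bool = False
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Background point charges embedding one fragment.

    Returns ``(coords, charges)`` of every protein and ligand atom (plus
    solvent/ion atoms when ``include_solvent``) not in the fragment's
    real+cap member set.  Link atoms never appear in backgrounds.
    """
    if fragment not in scheme.fragments:
        raise ValueError("fragment does not belong to this scheme")
    members = set(fragment.member_atoms)
    segs = {Segment.PROTEIN, Segment.LIGAND}
    if include_solvent:
        segs |= {Segment.SOLVENT, Segment.ION}
    idx = [i for i, a in enumerate(system.atoms)
           if a.segment in segs and i not in members]
    idx = np.asarray(idx, dtype=int)
    return system.coords[idx], system.charges[idx]
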