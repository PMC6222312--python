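"""ESP-evaluation backends for fragment assembly.

A backend is a pure function of an :class:`ESPRequest` (fragment atoms, link
atoms, embedding background, evaluation points) returning an
:class:`ESPResult` (one potential per point, volts).

Two backends ship:

``surrogate``
    The additive point-charge surrogate: the potential is the Coulomb sum
    over the fragment's real+cap atoms' partial charges; link atoms carry no
    charge and the background is ignored (no polarization).  Being exactly
    additive over atoms, the surrogate makes the signed fragment assembly
    telescope to the whole-system potential at machine precision — it is the
    oracle every assembly test leans on, and the desk-scale default.

``qm``
    An adapter to an external quantum-chemistry engine (PySCF).  The fragment
    (with link hydrogens) is solved in the field of the background point
    charges and the full electronic + nuclear ESP is evaluated at the
    requested points.  Results are cached on disk keyed by a content hash of
    the request.  If no engine is installed the backend raises
    :class:`BackendUnavailableError` — never a silent fallback.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import COULOMB_K_V_ANG, HARTREE_TO_VOLT, BOHR_TO_ANG

__all__ = [
    "ESPRequest",
    "ESPResult",
    "BackendUnavailableError",
    "SurrogateBackend",
    "QMBackend",
    "surrogate_esp",
    "external_qm_esp",
    "get_backend",
]

_MIN_POINT_DISTANCE = 1e-3  # Å, points must stay off fragment nuclei


class BackendUnavailableError(RuntimeError):
    """The requested external engine is not installed or not reachable."""


@dataclass(frozen=True)
class ESPRequest:
    """Everything a backend needs: fragment content, embedding, points."""

    elements: tuple[str, ...]
    coords: np.ndarray          # (n, 3) fragment real+cap atoms, Å
    charges: np.ndarray         # (n,) partial charges of those atoms, e
    link_positions: np.ndarray  # (m, 3) capping hydrogens, Å
    net_charge: int
    background_coords: np.ndarray   # (k, 3)
    background_charges: np.ndarray  # (k,)
    points: np.ndarray          # (p, 3) evaluation points, Å
    eps_eff: float = 1.0
    fragment_id: str = ""

    def __post_init__(self) -> None:
        for name in ("coords", "charges", "link_positions",
                     "background_coords", "background_charges", "points"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if self.points.size and self.coords.size:
            from scipy.spatial.distance import cdist
            d = cdist(self.points, self.coords)
            if d.min() <= _MIN_POINT_DISTANCE:
                raise ValueError(
                    f"{self.fragment_id or 'request'}: an evaluation point "
                    f"lies on a fragment nucleus (d={d.min():.2e} Å)")

    def content_hash(self) -> str:
        """SHA-256 of the request content, coordinates rounded to 1e-6 Å."""
        payload = {
            "elements": list(self.elements),
            "coords": np.round(self.coords, 6).tolist(),
            "charges": np.round(self.charges, 6).tolist(),
            "links": np.round(self.link_positions, 6).tolist(),
            "net_charge": self.net_charge,
            "bg_coords": np.round(self.background_coords, 6).tolist(),
            "bg_charges": np.round(self.background_charges, 6).tolist(),
            "points": np.round(self.points, 6).tolist(),
            "eps_eff": self.eps_eff,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass(frozen=True)
class ESPResult:
    potentials: np.ndarray  # volts, one per requested point
    backend_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "potentials",
                           np.asarray(self.potentials, dtype=float))
        if not np.all(np.isfinite(self.potentials)):
            raise ValueError("non-finite backend potentials")


class SurrogateBackend:
    """Additive point-charge ESP: exact, polarization-free, background-blind."""

    backend_id = "surrogate"

    def __call__(self, req: ESPRequest) -> ESPResult:
        return surrogate_esp(req)


def surrogate_esp(req: ESPRequest) -> ESPResult:
    """Coulomb ESP of the fragment's point charges at the requested points.

    Link atoms carry zero charge; the background is ignored.  Strictly
    additive over atoms by construction.
    """
    if req.points.size == 0:
        return ESPResult(potentials=np.empty(0), backend_id="surrogate")
    if req.coords.size == 0:
        return ESPResult(potentials=np.zeros(len(req.points)),
                         backend_id="surrogate")
    from scipy.spatial.distance import cdist
    d = cdist(req.points, req.coords)
    v = COULOMB_K_V_ANG / req.eps_eff * (1.0 / d) @ req.charges
    return ESPResult(potentials=v, backend_id="surrogate")


class QMBackend:
    """Adapter to a PySCF engine with on-disk result caching.

    The documented production settings are a hybrid meta-GGA functional with
    a polarized double-zeta basis (M06-2X/6-31G**); tests pin a minimal basis
    for speed.  The adapter requests the full (electronic + nuclear) ESP.
    """

    backend_id = "qm"

    def __init__(self, method: str = "M06-2X", basis: str = "6-31G**",
                 cache_dir: str | Path | None = None):
        self.method = method
        self.basis = basis
        self.cache_dir = Path(cache_dir) if cache_dir else None

    def __call__(self, req: ESPRequest) -> ESPResult:
        return external_qm_esp(req, self.method, self.basis, self.cache_dir)


def external_qm_esp(req: ESPRequest, method: str, basis: str,
                    cache_dir: str | Path | None = None) -> ESPResult:
    """Fragment ESP from a converged wavefunction in the background field.

    Raises :class:`BackendUnavailableError` when no engine is installed, and
    a RuntimeError naming the fragment on SCF non-convergence.  Results are
    cached as JSON keyed by :meth:`ESPRequest.content_hash`.
    """
    cache_path = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = hashlib.sha256(
            f"{req.content_hash()}|{method}|{basis}".encode()).hexdigest()
        cache_path = cache_dir / f"{key}.json"
        if cache_path.exists():
            data = json.loads(cache_path.read_text())
            return ESPResult(potentials=np.asarray(data["potentials"]),
                             backend_id="qm", metadata=data["metadata"])

    try:
        from pyscf import gto, scf, dft  # noqa: F401
        from pyscf.qmmm import mm_charge
    except ImportError as exc:
        raise BackendUnavailableError(
            "QM backend requires PySCF, which is not installed; install the "
            "'qm' extra or select the surrogate backend") from exc

    atom_spec = [(el, tuple(xyz)) for el, xyz in zip(req.elements, req.coords)]
    atom_spec += [("H", tuple(xyz)) for xyz in req.link_positions]
    mol = gto.M(atom=atom_spec, basis=basis, charge=int(req.net_charge),
                spin=0, unit="Angstrom")
    if method.upper() in ("HF", "RHF"):
        mf = scf.RHF(mol)
    else:
        mf = dft.RKS(mol)
        mf.xc = method
    if len(req.background_charges):
        mf = mm_charge(mf, req.background_coords, req.background_charges,
                       unit="Angstrom")
    mf.kernel()
    if not mf.converged:
        raise RuntimeError(f"SCF failed to converge for fragment "
                           f"{req.fragment_id or '<anonymous>'}")

    pts_bohr = req.points / BOHR_TO_ANG
    dm = mf.make_rdm1()
    # nuclear part
    nuc = np.zeros(len(req.points))
    for z, coord in zip(mol.atom_charges(), mol.atom_coords()):
        nuc += z / np.linalg.norm(pts_bohr - coord, axis=1)
    # electronic part via charge-distribution integrals at the grid points
    fakemol = gto.fakemol_for_charges(pts_bohr)
    from pyscf import df
    ints = df.incore.aux_e2(mol, fakemol)
    elec = np.einsum("ijp,ij->p", ints, dm)
    v_au = nuc - elec
    potentials = v_au * HARTREE_TO_VOLT
    metadata = {"method": method, "basis": basis,
                "e_tot": float(mf.e_tot), "n_atoms": mol.natm}
    if cache_path is not None:
        cache_path.write_text(json.dumps(
            {"potentials": potentials.tolist(), "metadata": metadata}))
    return ESPResult(potentials=potentials, backend_id="qm",
                     metadata=metadata)


def get_backend(name: str, **kwargs):
    """Select a backend by config name: ``surrogate`` or ``qm``."""
    if name == "surrogate":
        return SurrogateBackend()
    if name == "qm":
        return QMBackend(**kwargs)
    raise ValueError(f"unknown backend {name!r}")
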