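"""Atomic model handling: PDB/mmCIF I/O, solvent chain assignment with
symmetry-aware occupancies, asymmetric-unit extraction, and rigid-body
superposition.

A :class:`StructureModel` is an ordered collection of :class:`AtomRecord`
partitioned into protein atoms, water oxygens and monoatomic ions. Models
from different solution conditions (pH values here) are superposed onto a
common reference before any cross-condition water analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

WATER_RESIDUE_NAMES = {"HOH", "WAT", "H2O", "DOD"}

#: residue names of common monoatomic ions as deposited in the PDB
ION_RESIDUE_NAMES = {
    "FE", "FE2", "FE3", "MG", "MN", "ZN", "NA", "K", "CL", "CA",
    "CU", "CU1", "NI", "CO", "CD", "BR", "IOD", "CS", "LI", "RB", "SR", "BA",
}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class ModelError(Exception):
    """Base class for structural-model errors."""


class FormatError(ModelError):
    """The input file could not be parsed under the named format."""


class EmptyModelError(ModelError):
    """The parsed file contains no atoms."""


class ChainNotFoundError(ModelError):
    """A requested chain is not present in the model."""


class SuperpositionError(ModelError):
    """Atom pairing for superposition failed."""


@dataclass
class AtomRecord:
    """One atom: element, identity within the residue hierarchy, position (Å),
    occupancy and isotropic B-factor (Å²)."""

    element: str
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")
        if not self.element:
            raise ValueError("element must be non-empty")
        self.element = self.element.upper()

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESIDUE_NAMES

    @property
    def is_ion(self) -> bool:
        return self.residue_name in ION_RESIDUE_NAMES

    @property
    def is_protein(self) -> bool:
        return not (self.is_water or self.is_ion)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


class StructureModel:
    """An atomic model for one condition, partitioned into protein atoms,
    water oxygens and ions.

    The partitions are disjoint and cover all atoms: waters by residue name
    (HOH and synonyms), monoatomic ions by residue name, everything else
    protein. ``superposed`` records whether the model has been brought into
    the ensemble's common reference frame.
    """

    def __init__(self, atoms: Iterable[AtomRecord], condition_label: str = "",
                 superposed: bool = False):
        self.atoms: list[AtomRecord] = list(atoms)
        self.condition_label = condition_label
        self.superposed = superposed
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            if self.atoms:
                self._coords = np.array([a.position for a in self.atoms])
            else:
                self._coords = np.empty((0, 3))
        return self._coords

    # -- partitions ---------------------------------------------------------

    def protein_atoms(self, heavy_only: bool = False) -> list[AtomRecord]:
        return [a for a in self.atoms
                if a.is_protein and not (heavy_only and a.is_hydrogen)]

    def water_oxygens(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_water and a.element == "O"]

    def ions(self, element: str | None = None) -> list[AtomRecord]:
        sel = [a for a in self.atoms if a.is_ion]
        if element is not None:
            sel = [a for a in sel if a.element == element.upper()]
        return sel

    def protein_coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.protein_atoms(heavy_only=heavy_only)
        return np.array([a.position for a in atoms]) if atoms else np.empty((0, 3))

    def water_coords(self) -> np.ndarray:
        waters = self.water_oxygens()
        return np.array([a.position for a in waters]) if waters else np.empty((0, 3))

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return sorted(seen)

    @property
    def protein_chains(self) -> list[str]:
        return sorted({a.chain_id for a in self.atoms if a.is_protein})

    # -- transforms ---------------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    superposed: bool = True) -> "StructureModel":
        """Return a copy with every atom position mapped to R·x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_atoms = [replace(a, position=rotation @ a.position + translation)
                     for a in self.atoms]
        return StructureModel(new_atoms, self.condition_label, superposed=superposed)

    def copy(self) -> "StructureModel":
        return StructureModel([replace(a) for a in self.atoms],
                              self.condition_label, self.superposed)


# ---------------------------------------------------------------------------
# I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise FormatError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_structure(path: str | Path, format: str | None = None,
                   condition_label: str = "") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records of the first model are kept. Alternate locations
    are collapsed to the highest-occupancy conformer of each atom; insertion
    codes are dropped (residues keep their numeric seqid).
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"failed to parse {path} as {fmt}: {exc}") from exc

    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise EmptyModelError(f"{path} contains no coordinate model")
    model = st[0]
    for chain in model:
        for residue in chain:
            # collapse altlocs: keep the highest-occupancy conformer per atom name
            best: dict[str, "gemmi.Atom"] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                occ = atom.occ if atom.occ > 0 else 1.0
                atoms.append(AtomRecord(
                    element=atom.element.name,
                    atom_name=atom.name,
                    residue_name=residue.name,
                    residue_id=residue.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(occ, 1.0),
                    b_factor=atom.b_iso,
                ))
    if not atoms:
        raise EmptyModelError(f"{path} contains no atoms")
    return StructureModel(atoms, condition_label=condition_label)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB (3-decimal coordinate precision)."""
    import gemmi

    # gemmi's add_* methods copy their argument, so build bottom-up:
    # group atoms into residues/chains first, then assemble.
    chain_order: list[str] = []
    residues_by_chain: dict[str, list[tuple[tuple, list[AtomRecord]]]] = {}
    for a in model.atoms:
        if a.chain_id not in residues_by_chain:
            residues_by_chain[a.chain_id] = []
            chain_order.append(a.chain_id)
        res_list = residues_by_chain[a.chain_id]
        key = (a.residue_id, a.residue_name)
        if not res_list or res_list[-1][0] != key:
            res_list.append((key, []))
        res_list[-1][1].append(a)

    st = gemmi.Structure()
    gmodel = gemmi.Model("1")
    for chain_id in chain_order:
        ch = gemmi.Chain(chain_id)
        for (resid, resname), records in residues_by_chain[chain_id]:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resid, " ")
            res.het_flag = "H" if records[0].is_water or records[0].is_ion else "A"
            for a in records:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element.capitalize())
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                res.add_atom(atom)
            ch.add_residue(res)
        gmodel.add_chain(ch)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Solvent chain assignment
# ---------------------------------------------------------------------------

#: symmetry-axis occupancies as deposited (two-, three-, fourfold)
SYMMETRY_OCCUPANCY = {1: 1.0, 2: 0.5, 3: 0.33, 4: 0.25}


def _chain_atom_indices(model: StructureModel) -> np.ndarray:
    """Ordinal index of each protein atom within its own chain."""
    counters: dict[str, int] = {}
    idx = np.empty(len(model.atoms), dtype=int)
    for i, a in enumerate(model.atoms):
        if a.is_protein:
            k = counters.get(a.chain_id, 0)
            idx[i] = k
            counters[a.chain_id] = k + 1
        else:
            idx[i] = -1
    return idx


def assign_solvent_chain(solvent_atom: AtomRecord, model: StructureModel,
                         tol: float = 1e-3) -> tuple[str, float]:
    """Assign a water or ion to the chain of its nearest protein atom.

    If several chains tie for the minimum distance within ``tol`` and the
    tying atoms occupy the same ordinal position within their chains — the
    signature of a molecule sitting on a symmetry axis — the solvent atom is
    shared: occupancy 0.5 / 0.33 / 0.25 for two-/three-/fourfold multiplicity
    and the alphabetically first tying chain. Ties between unrelated atoms
    keep occupancy 1.0 on the alphabetically first chain.
    """
    prot_idx = [i for i, a in enumerate(model.atoms) if a.is_protein]
    if not prot_idx:
        raise ModelError("model has no protein atoms to assign solvent against")
    prot_coords = model.coords[prot_idx]
    d = np.linalg.norm(prot_coords - solvent_atom.position, axis=1)
    dmin = d.min()
    tie = np.flatnonzero(d <= dmin + tol)
    within_chain = _chain_atom_indices(model)
    tie_chains = [model.atoms[prot_idx[j]].chain_id for j in tie]
    tie_indices = [within_chain[prot_idx[j]] for j in tie]
    distinct_chains = sorted(set(tie_chains))
    if len(distinct_chains) > 1 and len(set(tie_indices)) == 1:
        mult = len(distinct_chains)
        occ = SYMMETRY_OCCUPANCY.get(mult, round(1.0 / mult, 2))
        return distinct_chains[0], occ
    return distinct_chains[0], 1.0


def assign_all_solvent(model: StructureModel, tol: float = 1e-3) -> StructureModel:
    """Return a copy with every water and ion reassigned via
    :func:`assign_solvent_chain`."""
    new_atoms = []
    for a in model.atoms:
        if a.is_protein:
            new_atoms.append(replace(a))
        else:
            chain, occ = assign_solvent_chain(a, model, tol=tol)
            new_atoms.append(replace(a, chain_id=chain, occupancy=occ))
    return StructureModel(new_atoms, model.condition_label, model.superposed)


def extract_chain(model: StructureModel, chain_id: str) -> StructureModel:
    """Isolate one chain (the asymmetric unit): its protein atoms plus the
    solvent and ions assigned to it."""
    available = model.chains
    if chain_id not in available:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not in model; available chains: {available}")
    atoms = [replace(a) for a in model.atoms if a.chain_id == chain_id]
    return StructureModel(atoms, model.condition_label, model.superposed)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """A least-squares rigid-body fit: x ↦ rotation·x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal rigid-body fit of paired coordinate sets (Kabsch/SVD)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("paired coordinate sets must both be (n, 3)")
    if len(P) < 3:
        raise SuperpositionError(f"need ≥3 paired atoms, got {len(P)}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    dev = P @ R.T + t - Q
    rmsd = float(np.sqrt((dev ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


def calpha(atom: AtomRecord) -> bool:
    """Default superposition selection: Cα atoms."""
    return atom.is_protein and atom.atom_name == "CA"


def superpose(mobile: StructureModel, reference: StructureModel,
              selection: Callable[[AtomRecord], bool] = calpha,
              min_pair_fraction: float = 0.9) -> SuperpositionResult:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Atoms are paired by (chain, residue_id, atom_name) within the selection.
    Unpaired selected atoms are skipped with a warning when ≥90% of the
    smaller selection pairs; otherwise the first unmatched atom is reported.
    The resulting transform applies to all atoms, waters included.
    """
    def keyed(model: StructureModel) -> dict:
        out = {}
        for a in model.atoms:
            if selection(a):
                out[(a.chain_id, a.residue_id, a.atom_name)] = a.position
        return out

    mob, ref = keyed(mobile), keyed(reference)
    common = [k for k in mob if k in ref]
    smaller = min(len(mob), len(ref))
    if smaller == 0:
        raise SuperpositionError("selection matched no atoms")
    frac = len(common) / smaller
    if frac < min_pair_fraction:
        unmatched = next(k for k in sorted(mob) if k not in ref) \
            if any(k not in ref for k in mob) else next(k for k in sorted(ref) if k not in mob)
        raise SuperpositionError(
            f"only {len(common)}/{smaller} selected atoms pair; "
            f"first unmatched atom: chain {unmatched[0]}, residue {unmatched[1]}, "
            f"atom {unmatched[2]}")
    if frac < 1.0:
        logger.warning("superpose: %d/%d selected atoms unpaired; skipped",
                       smaller - len(common), smaller)
    P = np.array([mob[k] for k in common])
    Q = np.array([ref[k] for k in common])
    return kabsch(P, Q)


def superpose_model(mobile: StructureModel, reference: StructureModel,
                    selection: Callable[[AtomRecord], bool] = calpha) -> tuple[StructureModel, SuperpositionResult]:
    """Superpose and return the transformed mobile model plus the fit."""
    fit = superpose(mobile, reference, selection)
    return mobile.transformed(fit.rotation, fit.translation), fit
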