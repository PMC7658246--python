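"""Molecular structures, atom selections and rigid-body superposition.

The in-memory representation is deliberately small: a :class:`MolecularStructure`
holds parallel arrays of atom names, residue identifiers, chain identifiers and
Cartesian coordinates (Angstrom).  The model class used downstream is
heavy-atom only, so hydrogens are dropped on input.  PDB parsing and writing is
delegated to :mod:`biotite`.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import numpy as np

__all__ = [
    "MolecularStructure",
    "AtomSelection",
    "StructureError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "geometric_center",
    "superpose",
]


class StructureError(ValueError):
    """Raised for malformed or empty structure input."""


class SelectionError(ValueError):
    """Raised when an atom selection cannot be resolved."""


# Backbone atom names.  Nucleotide backbone covers phosphate and ribose
# (both prime and legacy asterisk spellings); "functional group" selections
# return the complement, i.e. the base for nucleotides and the side chain
# (CB and beyond) for amino acids.
_NUC_BACKBONE = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    "O5*", "C5*", "C4*", "O4*", "C3*", "O3*", "C2*", "O2*", "C1*",
}
_AA_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_AA_NAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_NUC_NAMES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU",
              "RA", "RC", "RG", "RU"}


def _is_amino(res_name: str) -> bool:
    return res_name.upper() in _AA_NAMES


def _is_nucleotide(res_name: str) -> bool:
    return res_name.upper() in _NUC_NAMES


@dataclasses.dataclass
class MolecularStructure:
    """Heavy-atom structure: parallel per-atom arrays plus free-text metadata.

    Invariants: positions finite, at least one atom, and the
    (chain_id, residue_number, atom_name) triple unique per atom.
    """

    atom_name: np.ndarray      # (n,) str
    res_id: np.ndarray         # (n,) int
    res_name: np.ndarray       # (n,) str
    chain_id: np.ndarray       # (n,) str
    coord: np.ndarray          # (n, 3) float, Angstrom
    metadata: str = ""

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.coord = np.asarray(self.coord, dtype=np.float64)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atom_name)
        if n == 0:
            raise StructureError("structure contains no atoms")
        if self.coord.shape != (n, 3):
            raise StructureError(
                f"coordinate array shape {self.coord.shape} does not match "
                f"{n} atoms")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        triples = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(triples)) != n:
            seen: set = set()
            for t in triples:
                if t in seen:
                    raise StructureError(
                        f"duplicate atom identity {t!r}")
                seen.add(t)

    # -- convenience --------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def atom_key(self, i: int) -> tuple[str, int, str]:
        """(chain_id, residue_number, atom_name) identity of atom ``i``."""
        return (str(self.chain_id[i]), int(self.res_id[i]),
                str(self.atom_name[i]))

    def keys(self) -> list[tuple[str, int, str]]:
        return [self.atom_key(i) for i in range(self.n_atoms)]

    def residue_key(self, i: int) -> tuple[str, int]:
        return (str(self.chain_id[i]), int(self.res_id[i]))

    def copy(self, coord: np.ndarray | None = None) -> "MolecularStructure":
        return MolecularStructure(
            atom_name=self.atom_name.copy(),
            res_id=self.res_id.copy(),
            res_name=self.res_name.copy(),
            chain_id=self.chain_id.copy(),
            coord=self.coord.copy() if coord is None else np.asarray(coord),
            metadata=self.metadata,
        )


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AtomSelection:
    """Declarative atom selection.

    All non-``None`` fields must match simultaneously (logical AND).
    ``residues`` accepts integers and ``(lo, hi)`` inclusive ranges.
    ``group`` is one of ``"backbone"`` or ``"functional-group"`` (the
    non-backbone complement: nucleotide base, amino-acid side chain from CB).

    Selections can be parsed from strings such as
    ``"chain L and resnum 2-5 and name BD"`` or
    ``"resname U and group functional-group"``.
    """

    chain: str | None = None
    residues: Sequence[int | tuple[int, int]] | None = None
    resnames: Sequence[str] | None = None
    atom_names: Sequence[str] | None = None
    group: str | None = None

    @staticmethod
    def parse(expr: str) -> "AtomSelection":
        """Parse a selection expression (clauses joined by ``and``)."""
        sel = AtomSelection()
        expr = expr.strip()
        if not expr or expr.lower() == "all":
            return sel
        for clause in re.split(r"\s+and\s+", expr):
            parts = clause.split(None, 1)
            if len(parts) != 2:
                raise SelectionError(f"cannot parse clause {clause!r}")
            key, value = parts[0].lower(), parts[1].strip()
            if key == "chain":
                sel.chain = value
            elif key in ("resnum", "resid"):
                residues: list[int | tuple[int, int]] = []
                for tok in value.replace(",", " ").split():
                    if "-" in tok[1:]:
                        lo, hi = tok.rsplit("-", 1)
                        residues.append((int(lo), int(hi)))
                    else:
                        residues.append(int(tok))
                sel.residues = residues
            elif key == "resname":
                sel.resnames = value.replace(",", " ").split()
            elif key == "name":
                sel.atom_names = value.replace(",", " ").split()
            elif key == "group":
                sel.group = value
            else:
                raise SelectionError(f"unknown selection key {key!r}")
        return sel

    def _group_mask(self, structure: MolecularStructure) -> np.ndarray:
        if self.group not in ("backbone", "functional-group"):
            raise SelectionError(f"unknown group {self.group!r}")
        mask = np.zeros(structure.n_atoms, dtype=bool)
        for i in range(structure.n_atoms):
            rn = str(structure.res_name[i])
            an = str(structure.atom_name[i])
            if _is_nucleotide(rn):
                is_bb = an in _NUC_BACKBONE
            elif _is_amino(rn):
                is_bb = an in _AA_BACKBONE
            else:
                # single-bead / unknown chemistry: every atom is backbone and
                # the functional group degenerates to the whole residue
                is_bb = True
                if self.group == "functional-group":
                    mask[i] = True
                    continue
            mask[i] = is_bb if self.group == "backbone" else not is_bb
        return mask

    def mask(self, structure: MolecularStructure) -> np.ndarray:
        m = np.ones(structure.n_atoms, dtype=bool)
        if self.chain is not None:
            m &= structure.chain_id == self.chain
        if self.residues is not None:
            rm = np.zeros(structure.n_atoms, dtype=bool)
            for item in self.residues:
                if isinstance(item, tuple):
                    lo, hi = item
                    rm |= (structure.res_id >= lo) & (structure.res_id <= hi)
                else:
                    rm |= structure.res_id == item
            m &= rm
        if self.resnames is not None:
            m &= np.isin(structure.res_name, list(self.resnames))
        if self.atom_names is not None:
            m &= np.isin(structure.atom_name, list(self.atom_names))
        if self.group is not None:
            m &= self._group_mask(structure)
        return m

    def resolve(self, structure: MolecularStructure) -> np.ndarray:
        """Atom indices matching this selection; error if empty."""
        idx = np.flatnonzero(self.mask(structure))
        if idx.size == 0:
            raise SelectionError(f"selection {self!r} matches no atoms")
        return idx


def _as_selection(sel: "AtomSelection | str | None") -> AtomSelection:
    if sel is None:
        return AtomSelection()
    if isinstance(sel, str):
        return AtomSelection.parse(sel)
    return sel


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _looks_like_hydrogen(element: str, atom_name: str) -> bool:
    if element in ("H", "D"):
        return True
    if element:
        return False
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() in ("H", "D") and not stripped.upper().startswith("HG")


def _prescan_pdb(path: str) -> int:
    """Validate coordinate fields of ATOM/HETATM records.

    Returns the number of coordinate records; raises :class:`StructureError`
    naming the offending 1-based line number on malformed fields.
    """
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n_records += 1
            if len(line.rstrip("\n")) < 54:
                raise StructureError(
                    f"{path}: malformed coordinate record on line {lineno}")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as exc:
                raise StructureError(
                    f"{path}: malformed coordinates on line {lineno}: {exc}"
                ) from exc
    return n_records


def read_pdb(path: str, keep_hydrogens: bool = False) -> MolecularStructure:
    """Read a PDB file into a heavy-atom :class:`MolecularStructure`.

    One atom per ATOM/HETATM record; hydrogens are dropped unless
    ``keep_hydrogens``.  Alternate locations are resolved to the
    highest-occupancy conformer (first on ties).
    """
    import biotite.structure.io.pdb as pdb

    if _prescan_pdb(path) == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    try:
        pdb_file = pdb.PDBFile.read(path)
        atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    except StructureError:
        raise
    except Exception as exc:  # pragma: no cover - biotite error paths vary
        raise StructureError(f"{path}: PDB parse failure: {exc}") from exc

    keep = np.ones(atoms.array_length(), dtype=bool)
    if not keep_hydrogens:
        for i in range(atoms.array_length()):
            if _looks_like_hydrogen(str(atoms.element[i]),
                                    str(atoms.atom_name[i])):
                keep[i] = False
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no heavy atoms after hydrogen removal")
    return MolecularStructure(
        atom_name=np.asarray(atoms.atom_name),
        res_id=np.asarray(atoms.res_id),
        res_name=np.asarray(atoms.res_name),
        chain_id=np.asarray(atoms.chain_id),
        coord=np.asarray(atoms.coord, dtype=np.float64),
        metadata=f"read from {path}",
    )


def write_pdb(structure: MolecularStructure, path: str) -> None:
    """Write a structure as a single-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = structure.n_atoms
    atoms = struc.AtomArray(n)
    atoms.atom_name = structure.atom_name
    atoms.res_id = structure.res_id
    atoms.res_name = structure.res_name
    atoms.chain_id = structure.chain_id
    atoms.coord = structure.coord.astype(np.float32)
    atoms.element = np.array(
        [str(nm).strip()[:1].upper() or "X" for nm in structure.atom_name],
        dtype="U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def geometric_center(structure: MolecularStructure,
                     selection: "AtomSelection | str | None" = None
                     ) -> np.ndarray:
    """Unweighted mean position of the selected atoms (Angstrom)."""
    idx = _as_selection(selection).resolve(structure)
    return structure.coord[idx].mean(axis=0)


def superpose(mobile: MolecularStructure,
              reference: MolecularStructure,
              fit_selection: "AtomSelection | str | None" = None,
              ) -> tuple[MolecularStructure, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The optimal rotation/translation is computed on the atoms selected by
    ``fit_selection`` (matched by (chain, residue, atom-name) identity in both
    structures) and applied to every mobile atom.  Returns the transformed
    structure and the RMSD over the fit atoms.
    """
    from scipy.spatial.transform import Rotation

    sel = _as_selection(fit_selection)
    mob_idx = sel.resolve(mobile)
    ref_idx = sel.resolve(reference)
    ref_map = {reference.atom_key(int(i)): int(i) for i in ref_idx}
    pairs = [(int(i), ref_map[mobile.atom_key(int(i))])
             for i in mob_idx if mobile.atom_key(int(i)) in ref_map]
    if len(pairs) < 3:
        raise SelectionError(
            f"superposition needs >=3 shared fit atoms, found {len(pairs)}")
    mob_pts = mobile.coord[[p[0] for p in pairs]]
    ref_pts = reference.coord[[p[1] for p in pairs]]
    mob_c = mob_pts.mean(axis=0)
    ref_c = ref_pts.mean(axis=0)
    a = mob_pts - mob_c
    b = ref_pts - ref_c
    # collinear fit atoms leave a rotation degree of freedom undetermined
    s = np.linalg.svd(b, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise SelectionError("fit atoms are (near-)collinear")
    rot, _ = Rotation.align_vectors(b, a)
    new_coord = rot.apply(mobile.coord - mob_c) + ref_c
    fitted = mobile.copy(coord=new_coord)
    d = rot.apply(a) - b
    rmsd = float(np.sqrt((d ** 2).sum(axis=1).mean()))
    return fitted, rmsd
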