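"""Atom-level data model plus readers/writers for protein structures.

Three on-disk formats are supported:

* standard PDB ``ATOM``/``HETATM`` fixed-column records,
* the Tinker Cartesian ``.xyz`` dialect (atom-count header, per-atom
  connectivity columns),
* a per-atom induced-dipole table (TSV with header
  ``serial dx dy dz unit``), as produced by a polarizable-force-field
  energy minimization.  Dipoles are *consumed* by this package, never
  computed.

Coordinates are Angstrom throughout; dipoles are converted to Debye on
ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import (
    BACKBONE_HEAVY_ATOMS,
    DEBYE_IN_COULOMB_METER,
    IONIZABLE_RESIDUES,
    WATER_RESIDUES,
    X_H_BOND_CUTOFF,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "ResidueKey",
    "StructureFormatError",
    "read_pdb",
    "write_pdb",
    "read_tinker_xyz",
    "write_tinker_xyz",
    "read_dipole_table",
    "write_dipole_table",
    "attach_dipoles",
    "debye_to_cm",
    "cm_to_debye",
]

_KNOWN_ELEMENTS = ("C", "N", "O", "H", "S")


class StructureFormatError(ValueError):
    """Raised when a structure or dipole file violates its format."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, position and optional dipole."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    is_backbone: bool = False
    dipole: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(
                f"atom {self.serial} ({self.atom_name}): position must be a "
                f"finite 3-vector, got {self.position!r}"
            )
        object.__setattr__(self, "position", pos)
        if self.dipole is not None:
            dip = np.asarray(self.dipole, dtype=float)
            if dip.shape != (3,) or not np.all(np.isfinite(dip)):
                raise ValueError(
                    f"atom {self.serial}: dipole must be a finite 3-vector"
                )
            object.__setattr__(self, "dipole", dip)
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class ResidueKey:
    """Identifies one ionizable residue: chain, sequence number, type."""

    chain_id: str
    residue_seq: int
    residue_name: str

    def __post_init__(self) -> None:
        if self.residue_name not in IONIZABLE_RESIDUES:
            raise ValueError(
                f"residue_name must be one of {IONIZABLE_RESIDUES}, "
                f"got {self.residue_name!r}"
            )


@dataclass
class ProteinStructure:
    """An ordered collection of atoms with optional explicit bonds.

    ``bonds`` holds unordered serial pairs, typically taken from Tinker
    connectivity; PDB-sourced structures usually have ``bonds is None``.
    """

    atoms: list[AtomRecord]
    bonds: set[frozenset[int]] | None = None
    source_id: str = ""
    _by_serial: dict[int, AtomRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_serial = {}
        for atom in self.atoms:
            if atom.serial in self._by_serial:
                raise ValueError(f"duplicate atom serial {atom.serial}")
            self._by_serial[atom.serial] = atom
        if self.bonds is not None:
            for pair in self.bonds:
                if len(pair) != 2:
                    raise ValueError(f"self-bond or malformed bond pair {set(pair)}")
                for serial in pair:
                    if serial not in self._by_serial:
                        raise ValueError(
                            f"bond references unknown atom serial {serial}"
                        )

    def __len__(self) -> int:
        return len(self.atoms)

    def atom_by_serial(self, serial: int) -> AtomRecord:
        return self._by_serial[serial]

    def positions(self) -> np.ndarray:
        """All atom positions as an (N, 3) array, in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped by (chain_id, residue_seq, residue_name)."""
        groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for atom in self.atoms:
            groups.setdefault(
                (atom.chain_id, atom.residue_seq, atom.residue_name), []
            ).append(atom)
        return groups

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        found = [
            a
            for a in self.atoms
            if a.chain_id == key.chain_id
            and a.residue_seq == key.residue_seq
            and a.residue_name == key.residue_name
        ]
        if not found:
            raise KeyError(f"residue {key} not found in structure {self.source_id!r}")
        return found


def _element_from_name(atom_name: str, pdb_element: str = "") -> str:
    """Infer the element from a PDB atom name (or trust the element column)."""
    el = pdb_element.strip().capitalize()
    if el.upper() in _KNOWN_ELEMENTS:
        return el.upper()
    if el:  # e.g. "Na", "Fe" — retained as 'other'
        return "other" if el.upper() not in _KNOWN_ELEMENTS else el.upper()
    name = atom_name.strip()
    # PDB convention: names like "1HB2" lead with a digit for hydrogens
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    lead = stripped[0].upper()
    if lead in _KNOWN_ELEMENTS:
        return lead
    return "other"


def _assign_backbone_flags(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Set is_backbone: backbone heavy names, plus H bonded to backbone heavy.

    An H atom counts as backbone iff its covalent partner — the nearest
    heavy atom of the same residue within the X-H bond cutoff — is a
    backbone heavy atom.
    """
    by_res: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in atoms:
        by_res.setdefault((a.chain_id, a.residue_seq), []).append(a)

    out: list[AtomRecord] = []
    for atom in atoms:
        if atom.element != "H":
            flag = atom.atom_name in BACKBONE_HEAVY_ATOMS
        else:
            flag = False
            best = np.inf
            for other in by_res[(atom.chain_id, atom.residue_seq)]:
                if other.element == "H" or other.serial == atom.serial:
                    continue
                d = float(np.linalg.norm(atom.position - other.position))
                if d < best and d <= X_H_BOND_CUTOFF:
                    best = d
                    flag = other.atom_name in BACKBONE_HEAVY_ATOMS
        out.append(replace(atom, is_backbone=flag))
    return out


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> ProteinStructure:
    """Parse ATOM/HETATM records from a PDB file.

    Water HETATM records are skipped; other heteroatoms (ions, cofactors)
    are retained with their element parsed.  Raises
    :class:`StructureFormatError` naming the line number on an
    unparseable coordinate field, and on an empty structure.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record not in ("ATOM", "HETATM"):
                continue
            residue_name = line[17:20].strip()
            if record == "HETATM" and residue_name in WATER_RESIDUES:
                continue
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                residue_seq = int(line[22:26])
            except ValueError as exc:
                raise StructureFormatError(
                    f"{path.name}, line {lineno}: unparseable field ({exc})"
                ) from None
            atom_name = line[12:16].strip()
            chain_id = line[21].strip() or "A"
            element_col = line[76:78] if len(line) >= 78 else ""
            element = _element_from_name(atom_name, element_col)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=atom_name,
                    element=element,
                    residue_name=residue_name,
                    residue_seq=residue_seq,
                    chain_id=chain_id,
                    position=np.array([x, y, z]),
                )
            )
    if not atoms:
        raise StructureFormatError(f"{path.name}: no ATOM/HETATM records found")
    return ProteinStructure(
        atoms=_assign_backbone_flags(atoms), source_id=path.stem
    )


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as fixed-column ATOM records (3-decimal precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        for a in structure.atoms:
            name = a.atom_name
            # PDB column 13-16 convention: 1-3 char names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            el = a.element if a.element != "other" else ""
            fh.write(
                f"ATOM  {a.serial:>5d} {name_field} "
                f"{a.residue_name:<3s} {a.chain_id:1s}{a.residue_seq:>4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {el:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Tinker Cartesian .xyz
# ---------------------------------------------------------------------------

def read_tinker_xyz(path: str | Path) -> ProteinStructure:
    """Parse the Tinker Cartesian ``.xyz`` dialect with connectivity.

    The first line holds the atom count (optionally followed by a title);
    each atom line holds index, name, x, y, z, type code, and neighbor
    indices.  The format carries no residue information, so every atom is
    assigned residue UNK 1 on chain A; bonds from the per-line neighbor
    lists are deduplicated into a symmetric set.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise StructureFormatError(f"{path.name}: empty file")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureFormatError(
            f"{path.name}, line 1: expected an atom count"
        ) from None
    body = lines[1:]
    if len(body) != declared:
        raise StructureFormatError(
            f"{path.name}: header declares {declared} atoms, found {len(body)}"
        )
    atoms: list[AtomRecord] = []
    bonds: set[frozenset[int]] = set()
    neighbor_lists: list[tuple[int, list[int]]] = []
    for lineno, line in enumerate(body, start=2):
        parts = line.split()
        if len(parts) < 6:
            raise StructureFormatError(
                f"{path.name}, line {lineno}: too few fields"
            )
        try:
            idx = int(parts[0])
            x, y, z = (float(v) for v in parts[2:5])
            neighbors = [int(v) for v in parts[6:]]
        except ValueError as exc:
            raise StructureFormatError(
                f"{path.name}, line {lineno}: unparseable field ({exc})"
            ) from None
        name = parts[1]
        atoms.append(
            AtomRecord(
                serial=idx,
                atom_name=name,
                element=_element_from_name(name),
                residue_name="UNK",
                residue_seq=1,
                chain_id="A",
                position=np.array([x, y, z]),
            )
        )
        neighbor_lists.append((idx, neighbors))
    serials = {a.serial for a in atoms}
    for idx, neighbors in neighbor_lists:
        for nb in neighbors:
            if nb not in serials:
                raise StructureFormatError(
                    f"{path.name}: atom {idx} lists out-of-range neighbor {nb}"
                )
            if nb != idx:
                bonds.add(frozenset((idx, nb)))
    return ProteinStructure(
        atoms=_assign_backbone_flags(atoms), bonds=bonds, source_id=path.stem
    )


def write_tinker_xyz(structure: ProteinStructure, path: str | Path) -> None:
    """Write a Tinker-dialect .xyz with connectivity from structure.bonds."""
    path = Path(path)
    adj: dict[int, list[int]] = {a.serial: [] for a in structure.atoms}
    for pair in structure.bonds or ():
        i, j = sorted(pair)
        adj[i].append(j)
        adj[j].append(i)
    with open(path, "w") as fh:
        fh.write(f"{len(structure.atoms)}  {structure.source_id}\n")
        for k, a in enumerate(structure.atoms, start=1):
            nb = " ".join(str(s) for s in sorted(adj[a.serial]))
            fh.write(
                f"{a.serial:>6d}  {a.atom_name:<4s} "
                f"{a.position[0]:12.6f} {a.position[1]:12.6f} "
                f"{a.position[2]:12.6f} {k:>5d} {nb}\n"
            )


# ---------------------------------------------------------------------------
# Dipole tables
# ---------------------------------------------------------------------------

def debye_to_cm(value: np.ndarray | float) -> np.ndarray | float:
    return value * DEBYE_IN_COULOMB_METER


def cm_to_debye(value: np.ndarray | float) -> np.ndarray | float:
    return value / DEBYE_IN_COULOMB_METER


def read_dipole_table(path: str | Path) -> dict[int, np.ndarray]:
    """Read a per-atom induced-dipole TSV; returns serial -> 3-vector in Debye.

    Expected columns: ``serial dx dy dz unit`` with unit tag ``D`` or
    ``C.m`` (``C*m``/``Cm`` accepted).  C·m values are converted to Debye.
    """
    path = Path(path)
    result: dict[int, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].lower() == "serial":  # header
                continue
            if len(parts) != 5:
                raise StructureFormatError(
                    f"{path.name}, line {lineno}: expected 5 columns, "
                    f"got {len(parts)}"
                )
            try:
                serial = int(parts[0])
                vec = np.array([float(v) for v in parts[1:4]])
            except ValueError as exc:
                raise StructureFormatError(
                    f"{path.name}, line {lineno}: unparseable field ({exc})"
                ) from None
            unit = parts[4]
            if unit == "D":
                pass
            elif unit.replace("·", ".").replace("*", ".").lower() in ("c.m", "cm"):
                vec = cm_to_debye(vec)
            else:
                raise StructureFormatError(
                    f"{path.name}, line {lineno}: unknown unit tag {unit!r}"
                )
            if serial in result:
                raise StructureFormatError(
                    f"{path.name}, line {lineno}: duplicate serial {serial}"
                )
            result[serial] = vec
    return result


def write_dipole_table(
    dipoles: Mapping[int, np.ndarray], path: str | Path, unit: str = "D"
) -> None:
    if unit != "D":
        raise ValueError("dipole tables are written in Debye ('D') only")
    with open(path, "w") as fh:
        fh.write("serial\tdx\tdy\tdz\tunit\n")
        for serial in sorted(dipoles):
            d = np.asarray(dipoles[serial], dtype=float)
            fh.write(f"{serial}\t{d[0]:.9g}\t{d[1]:.9g}\t{d[2]:.9g}\tD\n")


def attach_dipoles(
    structure: ProteinStructure, dipoles: Mapping[int, np.ndarray]
) -> tuple[ProteinStructure, int]:
    """Return a copy of the structure with dipoles attached by serial.

    Every serial in the mapping must exist in the structure; unmatched
    atoms keep ``dipole=None``.  Returns (new structure, number attached).
    """
    known = {a.serial for a in structure.atoms}
    unknown = sorted(set(dipoles) - known)
    if unknown:
        raise ValueError(
            f"dipole table references serials absent from structure: {unknown}"
        )
    attached = 0
    new_atoms: list[AtomRecord] = []
    for atom in structure.atoms:
        if atom.serial in dipoles:
            new_atoms.append(
                replace(atom, dipole=np.asarray(dipoles[atom.serial], dtype=float))
            )
            attached += 1
        else:
            new_atoms.append(atom)
    return (
        ProteinStructure(
            atoms=new_atoms, bonds=structure.bonds, source_id=structure.source_id
        ),
        attached,
    )
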