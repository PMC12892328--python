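"""Per-residue graph assembly: 26-feature node matrix, adjacency, label.

A residue graph's nodes are the atoms of the target residue itself
(hydrogens included) — never the surrounding context atoms; the
microenvironment enters exclusively through the count / hydrogen-bond /
SASA features.  Edges are the residue's covalent bonds plus a self-loop
on every node.

Feature layout (fixed order, see :class:`FeatureSchema`):

====  ======================================================
slot  content
====  ======================================================
1-4   residue type one-hot (ASP, GLU, HIS, LYS — alphabetical)
5-7   atom x, y, z in the residue's local frame (Angstrom)
8-10  induced dipole dx, dy, dz in the local frame (Debye)
11-14 heavy-atom neighbor counts C, N, O, S (context atoms)
15-16 hydrogen bonds as acceptor, as donor
17    SASA of the atom (Angstrom^2)
18-26 atom-type one-hot: N/C/O/H split backbone vs side chain,
      plus a single S slot
====  ======================================================

Slots 11-16 are min-max normalized across the entire dataset after
extraction; all other slots are left on their physical scales.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    HEAVY_HEAVY_BOND_CUTOFF,
    IONIZABLE_RESIDUES,
    X_H_BOND_CUTOFF,
)
from .local_frame import (
    DegenerateGeometryError,
    LocalFrame,
    build_local_frame,
    rotate_vector,
    to_local,
)
from .microenvironment import (
    ResidueEnvironment,
    compute_sasa,
    count_heavy_neighbors,
    crop_environment,
    detect_hydrogen_bonds,
)
from .residue_templates import RESIDUE_TEMPLATES, template_bond_serial_pairs
from .structure_io import AtomRecord, ProteinStructure, ResidueKey

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSchema",
    "ResidueGraph",
    "N_FEATURES",
    "build_adjacency",
    "featurize_nodes",
    "normalize_dataset",
    "apply_normalization",
    "build_dataset",
    "save_dataset",
    "load_dataset",
    "read_label_table",
    "DATASET_SCHEMA_VERSION",
]

N_FEATURES = 26
DATASET_SCHEMA_VERSION = "pkagraph-v1"

_ATOM_TYPE_SLOTS = (
    "N-bb", "N-sc", "C-bb", "C-sc", "O-bb", "O-sc", "H-bb", "H-sc", "S",
)


class FeatureSchema:
    """Names and index blocks of the 26 node-feature slots."""

    SLOT_NAMES: tuple[str, ...] = (
        "res_ASP", "res_GLU", "res_HIS", "res_LYS",
        "x_local", "y_local", "z_local",
        "dipole_dx", "dipole_dy", "dipole_dz",
        "n_neighbors_C", "n_neighbors_N", "n_neighbors_O", "n_neighbors_S",
        "hbonds_acceptor", "hbonds_donor",
        "sasa",
        *(f"atomtype_{t}" for t in _ATOM_TYPE_SLOTS),
    )
    RESIDUE_ONEHOT = slice(0, 4)
    COORDS = slice(4, 7)
    DIPOLE = slice(7, 10)
    NEIGHBOR_COUNTS = slice(10, 14)
    HBONDS = slice(14, 16)
    SASA = 16
    ATOM_TYPE_ONEHOT = slice(17, 26)
    NORMALIZED = slice(10, 16)  # slots 11-16 (counts + H-bonds)

    @classmethod
    def atom_type_index(cls, element: str, is_backbone: bool) -> int:
        if element == "S":
            return 17 + _ATOM_TYPE_SLOTS.index("S")
        tag = f"{element}-{'bb' if is_backbone else 'sc'}"
        try:
            return 17 + _ATOM_TYPE_SLOTS.index(tag)
        except ValueError:
            raise ValueError(
                f"element {element!r} cannot be one-hot encoded"
            ) from None


assert len(FeatureSchema.SLOT_NAMES) == N_FEATURES


@dataclass
class ResidueGraph:
    """One target residue as a graph: features, adjacency, pKa label."""

    key: ResidueKey
    node_features: np.ndarray  # (N, 26)
    adjacency: np.ndarray  # (N, N) binary, symmetric, unit diagonal
    label: float
    radius: float
    source_id: str = ""
    atom_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.node_features.shape[0]
        if self.node_features.shape != (n, N_FEATURES):
            raise ValueError(
                f"node_features must be (N, {N_FEATURES}), "
                f"got {self.node_features.shape}"
            )
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.diag(self.adjacency) == 1):
            raise ValueError("adjacency diagonal must be all ones (self-loops)")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def build_adjacency(
    env: ResidueEnvironment,
    bonds: set[frozenset[int]] | None = None,
) -> np.ndarray:
    """Binary adjacency over the target residue's atoms, with self-loops.

    Bond source priority: explicit bonds (Tinker connectivity) filtered to
    intra-residue pairs; else the per-residue bond template; else a
    distance fallback (heavy-heavy <= 1.9 A, X-H <= 1.2 A).  Context atoms
    never get edges.  A disconnected heavy-atom skeleton logs a warning.
    """
    atoms = env.self_atoms
    n = len(atoms)
    serial_to_idx = {a.serial: i for i, a in enumerate(atoms)}
    A = np.eye(n)

    pairs: set[frozenset[int]] = set()
    if bonds:
        pairs = {
            p for p in bonds if all(s in serial_to_idx for s in p)
        }
    if not pairs and env.key.residue_name in RESIDUE_TEMPLATES:
        name_to_serial = {a.atom_name: a.serial for a in atoms}
        pairs = template_bond_serial_pairs(env.key.residue_name, name_to_serial)
    if not pairs:  # distance fallback
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.linalg.norm(atoms[i].position - atoms[j].position))
                cutoff = (
                    X_H_BOND_CUTOFF
                    if "H" in (atoms[i].element, atoms[j].element)
                    else HEAVY_HEAVY_BOND_CUTOFF
                )
                if d <= cutoff:
                    pairs.add(frozenset((atoms[i].serial, atoms[j].serial)))

    for pair in pairs:
        i, j = (serial_to_idx[s] for s in pair)
        A[i, j] = A[j, i] = 1.0

    # connectivity check on the heavy-atom skeleton
    heavy_idx = [i for i, a in enumerate(atoms) if a.is_heavy]
    if len(heavy_idx) > 1:
        sub = A[np.ix_(heavy_idx, heavy_idx)]
        reach = np.linalg.matrix_power(
            np.minimum(sub + np.eye(len(heavy_idx)), 1.0), len(heavy_idx)
        )
        if np.any(reach[0] == 0):
            logger.warning(
                "heavy-atom graph of %s is disconnected", env.key
            )
    return A


def featurize_nodes(
    env: ResidueEnvironment,
    frame: LocalFrame,
    hbonds: Mapping[int, tuple[int, int]],
    sasa: Mapping[int, float],
    count_radius: float | None = None,
) -> np.ndarray:
    """The (N, 26) node-feature matrix for the target residue's atoms.

    Coordinates and dipole vectors are expressed in the residue's local
    frame; neighbor counts use the context atoms only, within
    ``count_radius`` (defaulting to the environment's crop radius) of
    each atom.  Atoms without a dipole get zeros (with a logged warning).
    """
    if count_radius is None:
        count_radius = env.radius
    res_onehot = np.zeros(4)
    res_onehot[IONIZABLE_RESIDUES.index(env.key.residue_name)] = 1.0

    rows = []
    missing_dipoles = []
    for atom in env.self_atoms:
        row = np.zeros(N_FEATURES)
        row[FeatureSchema.RESIDUE_ONEHOT] = res_onehot
        row[FeatureSchema.COORDS] = to_local(frame, atom.position)
        if atom.dipole is not None:
            row[FeatureSchema.DIPOLE] = rotate_vector(frame, atom.dipole)
        else:
            missing_dipoles.append(atom.serial)
        row[FeatureSchema.NEIGHBOR_COUNTS] = count_heavy_neighbors(
            env, atom, count_radius
        )
        acc, don = hbonds.get(atom.serial, (0, 0))
        row[FeatureSchema.HBONDS] = (acc, don)
        row[FeatureSchema.SASA] = sasa[atom.serial]
        row[FeatureSchema.atom_type_index(atom.element, atom.is_backbone)] = 1.0
        rows.append(row)
    if missing_dipoles:
        logger.warning(
            "%s: %d atoms without dipole vectors (zero-filled)",
            env.key, len(missing_dipoles),
        )
    return np.array(rows)


# ---------------------------------------------------------------------------
# Dataset-level normalization
# ---------------------------------------------------------------------------

def normalize_dataset(
    graphs: Sequence[ResidueGraph],
) -> tuple[list[ResidueGraph], dict[str, np.ndarray]]:
    """Min-max scale slots 11-16 to [0, 1] using dataset-wide extrema.

    The extrema are pooled over all nodes of all graphs; slots that are
    constant across the dataset map to 0.  Returns new graphs plus the
    constants for reuse at inference time.
    """
    if not graphs:
        raise ValueError("cannot normalize an empty dataset")
    sl = FeatureSchema.NORMALIZED
    pooled = np.vstack([g.node_features[:, sl] for g in graphs])
    mins = pooled.min(axis=0)
    maxs = pooled.max(axis=0)
    constants = {"min": mins, "max": maxs}
    return apply_normalization(graphs, constants), constants


def apply_normalization(
    graphs: Sequence[ResidueGraph], constants: Mapping[str, np.ndarray]
) -> list[ResidueGraph]:
    """Apply stored min-max constants to slots 11-16 (idempotent reuse)."""
    sl = FeatureSchema.NORMALIZED
    mins = np.asarray(constants["min"], dtype=float)
    maxs = np.asarray(constants["max"], dtype=float)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    out = []
    for g in graphs:
        feats = g.node_features.copy()
        scaled = (feats[:, sl] - mins) / safe
        scaled[:, span <= 0] = 0.0
        feats[:, sl] = scaled
        out.append(replace(g, node_features=feats))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def read_label_table(path: str | Path) -> pd.DataFrame:
    """Load a pKa label CSV with header ``pdb_id,chain,resnum,restype,pka_exp``."""
    df = pd.read_csv(path)
    required = {"pdb_id", "chain", "resnum", "restype", "pka_exp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return df


def build_dataset(
    structures: ProteinStructure | Mapping[str, ProteinStructure],
    labels: pd.DataFrame,
    radius: float = 9.0,
    count_radius: float | None = None,
    sasa_points: int = 960,
) -> tuple[list[ResidueGraph], list[dict]]:
    """One graph per labeled ionizable residue; returns (graphs, skip report).

    ``structures`` may be a single structure or a mapping from pdb_id.
    Residues of unsupported types, or failing C-alpha / frame
    construction, are skipped with a recorded reason.  Raises if zero
    graphs are produced.
    """
    if isinstance(structures, ProteinStructure):
        structures = {structures.source_id: structures}

    # per-structure descriptor caches
    hbond_cache: dict[str, Mapping] = {}
    sasa_cache: dict[str, Mapping] = {}

    graphs: list[ResidueGraph] = []
    skipped: list[dict] = []

    def skip(row, reason: str) -> None:
        skipped.append(
            {"pdb_id": row.pdb_id, "chain": row.chain, "resnum": row.resnum,
             "restype": row.restype, "reason": reason}
        )
        logger.info("skipping %s/%s%s: %s", row.pdb_id, row.chain,
                    row.resnum, reason)

    for row in labels.itertuples(index=False):
        pdb_id = str(row.pdb_id)
        if pdb_id not in structures:
            skip(row, f"structure {pdb_id!r} not provided")
            continue
        structure = structures[pdb_id]
        restype = str(row.restype).upper()
        if restype not in IONIZABLE_RESIDUES:
            skip(row, f"unsupported residue type {restype}")
            continue
        key = ResidueKey(str(row.chain), int(row.resnum), restype)
        try:
            env = crop_environment(structure, key, radius)
        except (KeyError, ValueError) as exc:
            skip(row, str(exc))
            continue
        by_name = {a.atom_name: a for a in env.self_atoms}
        if not {"CA", "C", "O"} <= set(by_name):
            skip(row, "missing frame anchor atoms (CA/C/O)")
            continue
        try:
            frame = build_local_frame(
                by_name["CA"].position, by_name["C"].position,
                by_name["O"].position,
            )
        except DegenerateGeometryError as exc:
            skip(row, f"degenerate frame geometry: {exc}")
            continue
        if pdb_id not in hbond_cache:
            hbond_cache[pdb_id] = detect_hydrogen_bonds(structure)
            sasa_cache[pdb_id] = compute_sasa(structure, n_points=sasa_points)
        features = featurize_nodes(
            env, frame, hbond_cache[pdb_id], sasa_cache[pdb_id],
            count_radius=count_radius,
        )
        adjacency = build_adjacency(env, structure.bonds)
        graphs.append(
            ResidueGraph(
                key=key,
                node_features=features,
                adjacency=adjacency,
                label=float(row.pka_exp),
                radius=radius,
                source_id=pdb_id,
                atom_names=tuple(a.atom_name for a in env.self_atoms),
            )
        )
    if not graphs:
        raise ValueError(
            f"no graphs produced ({len(skipped)} residues skipped)"
        )
    return graphs, skipped


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_dataset(
    graphs: Sequence[ResidueGraph],
    path: str | Path,
    normalization: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Lossless JSON archive of graphs (+ optional normalization constants)."""
    if not graphs:
        raise ValueError("refusing to save an empty dataset")
    payload = {
        "schema": DATASET_SCHEMA_VERSION,
        "graphs": [
            {
                "chain": g.key.chain_id,
                "resnum": g.key.residue_seq,
                "restype": g.key.residue_name,
                "node_features": g.node_features.tolist(),
                "adjacency": g.adjacency.astype(int).tolist(),
                "label": g.label,
                "radius": g.radius,
                "source_id": g.source_id,
                "atom_names": list(g.atom_names),
            }
            for g in graphs
        ],
    }
    if normalization is not None:
        payload["normalization"] = {
            k: np.asarray(v).tolist() for k, v in normalization.items()
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_dataset(
    path: str | Path,
) -> tuple[list[ResidueGraph], dict[str, np.ndarray] | None]:
    """Inverse of :func:`save_dataset`; errors on schema-version mismatch."""
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema")
    if version != DATASET_SCHEMA_VERSION:
        raise ValueError(
            f"dataset schema {version!r} does not match "
            f"{DATASET_SCHEMA_VERSION!r}"
        )
    graphs = [
        ResidueGraph(
            key=ResidueKey(g["chain"], g["resnum"], g["restype"]),
            node_features=np.array(g["node_features"], dtype=float),
            adjacency=np.array(g["adjacency"], dtype=float),
            label=g["label"],
            radius=g["radius"],
            source_id=g.get("source_id", ""),
            atom_names=tuple(g.get("atom_names", ())),
        )
        for g in payload["graphs"]
    ]
    norm = payload.get("normalization")
    if norm is not None:
        norm = {k: np.array(v, dtype=float) for k, v in norm.items()}
    return graphs, norm
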