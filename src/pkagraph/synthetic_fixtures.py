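"""Synthetic structures, dipoles and labels with known ground truth.

The generator builds multi-residue peptides with ideal backbone geometry
(C-alpha-C bond 1.53 A, C=O 1.23 A, planar carbonyl, 1.33 A peptide
links), interleaving ionizable residues with GLY/ALA spacers so that the
environment-derived features (neighbor counts, hydrogen bonds, SASA) are
non-trivial.  Every atom receives an isotropic zero-mean induced-dipole
vector, and labels can be planted as a known linear readout of the graph
features plus Gaussian noise — giving recovery experiments an exact
generative record to compare against.

Fixtures can be written to disk as standard PDB + dipole TSV + label
CSV, i.e. exactly the package's public input formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import IONIZABLE_RESIDUES, REFERENCE_PKA
from .graph_builder import (
    FeatureSchema,
    ResidueGraph,
    build_dataset,
    N_FEATURES,
)
from .residue_templates import RESIDUE_TEMPLATES, SPACER_RESIDUES
from .structure_io import AtomRecord, ProteinStructure

__all__ = [
    "FixtureSpec",
    "DEFAULT_PLANTED_COEFFICIENTS",
    "make_ideal_residue",
    "make_toy_protein",
    "planted_labels",
    "make_planted_dataset",
    "reference_label_table",
]

# Default planted mechanism: a sparse linear readout of mean-pooled node
# features, emulating the physics a pKa model should pick up — burial
# (SASA), local oxygen/carbon density, frame coordinates and the dipole
# field.  Scales are set against the raw (unnormalized) feature ranges so
# the planted shifts span roughly +/- 2 pKa units.
DEFAULT_PLANTED_COEFFICIENTS: np.ndarray = np.zeros(N_FEATURES)
DEFAULT_PLANTED_COEFFICIENTS[FeatureSchema.SASA] = 0.30
DEFAULT_PLANTED_COEFFICIENTS[12] = -0.60  # n_neighbors_O
DEFAULT_PLANTED_COEFFICIENTS[10] = -0.10  # n_neighbors_C
DEFAULT_PLANTED_COEFFICIENTS[4] = 0.80  # x_local
DEFAULT_PLANTED_COEFFICIENTS[7] = 2.00  # dipole_dx
DEFAULT_PLANTED_COEFFICIENTS.setflags(write=False)


@dataclass
class FixtureSpec:
    """Conditions for one synthetic peptide + label generation run."""

    n_residues: int = 16
    residue_types: Sequence[str] | None = None  # None: auto-interleaved
    dipole_scale: float = 0.5  # Debye, per-component std of induced dipoles
    noise_sd: float = 0.3  # pKa units
    planted_coefficients: np.ndarray = field(
        default_factory=lambda: DEFAULT_PLANTED_COEFFICIENTS.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_ideal_residue(
    residue_type: str,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    chain_id: str = "A",
    residue_seq: int = 1,
    serial_start: int = 1,
) -> list[AtomRecord]:
    """Instantiate one template residue at an arbitrary rigid pose."""
    if residue_type not in RESIDUE_TEMPLATES:
        raise ValueError(
            f"unsupported residue type {residue_type!r}; "
            f"supported: {sorted(RESIDUE_TEMPLATES)}"
        )
    tmpl = RESIDUE_TEMPLATES[residue_type]
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, float)
    positions = tmpl.positions @ R.T + t
    return [
        AtomRecord(
            serial=serial_start + i,
            atom_name=tmpl.atom_names[i],
            element=tmpl.elements[i],
            residue_name=residue_type,
            residue_seq=residue_seq,
            chain_id=chain_id,
            position=positions[i],
            is_backbone=tmpl.backbone_flags[i],
        )
        for i in range(tmpl.n_atoms)
    ]


def _small_rotation(rng: np.random.Generator, max_deg: float = 12.0) -> np.ndarray:
    """Random small rotation matrix (independent Euler angles <= max_deg)."""
    a, b, c = np.deg2rad(rng.uniform(-max_deg, max_deg, size=3))
    ca_, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    return rz @ ry @ rx


def _auto_types(n: int, rng: np.random.Generator) -> list[str]:
    """Ionizable residues at even positions, spacers at odd positions."""
    types = []
    for k in range(n):
        if k % 2 == 0:
            types.append(IONIZABLE_RESIDUES[(k // 2) % 4])
        else:
            types.append(SPACER_RESIDUES[int(rng.integers(len(SPACER_RESIDUES)))])
    return types


def make_toy_protein(
    spec: FixtureSpec, source_id: str = "toy"
) -> tuple[ProteinStructure, dict[int, np.ndarray]]:
    """Build a meandering peptide chain plus a per-atom dipole table.

    Residues are linked with 1.33 A peptide C-N bonds; consecutive rigid
    poses differ by small random rotations so C-alpha - C-alpha
    separations stay in the 3.0-4.2 A band of real backbones.  Dipole
    components are N(0, dipole_scale) Debye, seeded.
    """
    rng = np.random.default_rng(spec.seed)
    types = (
        list(spec.residue_types)
        if spec.residue_types is not None
        else _auto_types(spec.n_residues, rng)
    )
    if len(types) != spec.n_residues:
        raise ValueError("residue_types length must equal n_residues")

    atoms: list[AtomRecord] = []
    bonds: set[frozenset[int]] = set()
    serial = 1
    R = np.eye(3)
    t = np.zeros(3)
    prev_c_serial: int | None = None
    x_hat = np.array([1.0, 0.0, 0.0])

    for k, rtype in enumerate(types):
        tmpl = RESIDUE_TEMPLATES[rtype]
        if k > 0:
            prev_c_global = next(
                a.position for a in atoms
                if a.serial == prev_c_serial
            )
            direction = R @ x_hat + 0.08 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            n_global = prev_c_global + 1.33 * direction
            R = R @ _small_rotation(rng)
            n_local = tmpl.positions[tmpl.index_of("N")]
            t = n_global - R @ n_local
        res_atoms = make_ideal_residue(
            rtype, rotation=R, translation=t,
            chain_id="A", residue_seq=k + 1, serial_start=serial,
        )
        name_to_serial = {a.atom_name: a.serial for a in res_atoms}
        for a, b in tmpl.bonds:
            bonds.add(frozenset((name_to_serial[a], name_to_serial[b])))
        if prev_c_serial is not None:
            bonds.add(frozenset((prev_c_serial, name_to_serial["N"])))
        prev_c_serial = name_to_serial["C"]
        atoms.extend(res_atoms)
        serial += len(res_atoms)

    dipoles = {
        a.serial: rng.normal(0.0, spec.dipole_scale, size=3) for a in atoms
    }
    structure = ProteinStructure(atoms=atoms, bonds=bonds, source_id=source_id)
    return structure, dipoles


def reference_label_table(
    structure: ProteinStructure,
) -> pd.DataFrame:
    """Label table assigning each ionizable residue its reference pKa."""
    rows = []
    for (chain, seq, name), _atoms in sorted(structure.residues().items(),
                                             key=lambda kv: kv[0][1]):
        if name in IONIZABLE_RESIDUES:
            rows.append(
                {"pdb_id": structure.source_id, "chain": chain,
                 "resnum": seq, "restype": name,
                 "pka_exp": REFERENCE_PKA[name]}
            )
    return pd.DataFrame(rows)


def planted_labels(
    graphs: Sequence[ResidueGraph],
    coefficients: np.ndarray,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Plant labels as reference + coefficients . mean(features) + noise.

    Mutates each graph's ``label`` in place and returns the label vector
    plus the generative record (coefficients, noise draws, seed) so
    recovery experiments know the exact truth.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (N_FEATURES,):
        raise ValueError(
            f"coefficients must have length {N_FEATURES}, "
            f"got shape {coefficients.shape}"
        )
    rng = np.random.default_rng(seed)
    labels = np.empty(len(graphs))
    noiseless = np.empty(len(graphs))
    for i, g in enumerate(graphs):
        pooled = g.node_features.mean(axis=0)
        noiseless[i] = REFERENCE_PKA[g.key.residue_name] + float(
            coefficients @ pooled
        )
    noise = rng.normal(0.0, noise_sd, size=len(graphs)) if noise_sd > 0 else (
        np.zeros(len(graphs))
    )
    labels = noiseless + noise
    for g, val in zip(graphs, labels):
        g.label = float(val)
    record = {
        "coefficients": coefficients,
        "noise_sd": noise_sd,
        "seed": seed,
        "noiseless": noiseless,
    }
    return labels, record


def make_planted_dataset(
    n_graphs: int = 400,
    noise_sd: float = 0.3,
    seed: int = 0,
    radius: float = 9.0,
    residues_per_protein: int = 8,
    coefficients: np.ndarray | None = None,
    normalize: bool = True,
) -> tuple[list[ResidueGraph], dict]:
    """The planted-mechanism benchmark dataset used by recovery experiments.

    Builds enough toy peptides (``residues_per_protein`` ionizable
    residues each, spacers interleaved) to yield ``n_graphs`` residue
    graphs at the requested crop radius, plants labels with the default
    (or given) linear mechanism at noise level ``noise_sd``, then min-max
    normalizes the count features dataset-wide.
    """
    if coefficients is None:
        coefficients = DEFAULT_PLANTED_COEFFICIENTS
    n_proteins = int(np.ceil(n_graphs / residues_per_protein))
    structures: dict[str, ProteinStructure] = {}
    labels = []
    for p in range(n_proteins):
        spec = FixtureSpec(
            n_residues=2 * residues_per_protein,
            seed=(seed * 100003 + p) % (2**31),
            noise_sd=noise_sd,
        )
        sid = f"toy{p:04d}"
        structure, dipoles = make_toy_protein(spec, source_id=sid)
        from .structure_io import attach_dipoles

        structure, _ = attach_dipoles(structure, dipoles)
        structures[sid] = structure
        labels.append(reference_label_table(structure))
    label_df = pd.concat(labels, ignore_index=True)
    graphs, skipped = build_dataset(structures, label_df, radius=radius)
    graphs = graphs[:n_graphs]
    _, record = planted_labels(
        graphs, coefficients, noise_sd, seed=(seed * 7919 + 1) % (2**31)
    )
    record["skipped"] = skipped
    if normalize:
        from .graph_builder import normalize_dataset

        graphs, constants = normalize_dataset(graphs)
        record["normalization"] = constants
    return graphs, record
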