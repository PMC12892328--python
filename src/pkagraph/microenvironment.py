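"""Spherical microenvironment cropping and environment-derived descriptors.

For a target ionizable residue the local environment is the closed ball
of a chosen radius (7-11 A by convention) around its C-alpha.  From the
environment we derive per-atom descriptors that feed the node features:
heavy-atom neighbor counts by element, hydrogen-bond donor/acceptor
counts, and Shrake-Rupley solvent accessible surface area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import (
    SASA_PROBE_RADIUS,
    VDW_RADII,
    VDW_RADIUS_DEFAULT,
)
from .structure_io import AtomRecord, ProteinStructure, ResidueKey

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueEnvironment",
    "crop_environment",
    "count_heavy_neighbors",
    "detect_hydrogen_bonds",
    "compute_sasa",
]

# Geometric hydrogen-bond criterion (Baker-Hubbard-style):
HBOND_H_ACCEPTOR_CUTOFF: float = 2.5  # Angstrom, H...acceptor distance
HBOND_ANGLE_CUTOFF: float = 120.0  # degrees, donor-H-acceptor angle


@dataclass
class ResidueEnvironment:
    """Target-residue atoms plus all context atoms within the crop sphere."""

    key: ResidueKey
    radius: float
    self_atoms: list[AtomRecord]
    context_atoms: list[AtomRecord]


def crop_environment(
    structure: ProteinStructure, key: ResidueKey, radius: float
) -> ResidueEnvironment:
    """Crop the closed ball of ``radius`` around the residue's C-alpha.

    ``self_atoms`` are all atoms of the target residue (regardless of
    distance); ``context_atoms`` are all other atoms with
    ``|r - r_Calpha| <= radius``.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    self_atoms = structure.residue_atoms(key)  # raises KeyError if absent
    ca = [a for a in self_atoms if a.atom_name == "CA"]
    if not ca:
        raise ValueError(f"residue {key} has no C-alpha atom")
    center = ca[0].position
    self_serials = {a.serial for a in self_atoms}
    context = [
        a
        for a in structure.atoms
        if a.serial not in self_serials
        and float(np.linalg.norm(a.position - center)) <= radius
    ]
    return ResidueEnvironment(
        key=key, radius=radius, self_atoms=self_atoms, context_atoms=context
    )


def count_heavy_neighbors(
    env: ResidueEnvironment, atom: AtomRecord, radius: float
) -> tuple[int, int, int, int]:
    """Count context heavy atoms (C, N, O, S) within ``radius`` of ``atom``.

    Only atoms of *other* residues (the environment's context atoms)
    count; atoms of the target residue itself never do.  Hydrogens and
    other elements are excluded.
    """
    if atom.serial not in {a.serial for a in env.self_atoms}:
        raise ValueError(
            f"atom {atom.serial} is not part of the target residue {env.key}"
        )
    counts = {"C": 0, "N": 0, "O": 0, "S": 0}
    for other in env.context_atoms:
        if other.element not in counts:
            continue
        if float(np.linalg.norm(other.position - atom.position)) <= radius:
            counts[other.element] += 1
    return (counts["C"], counts["N"], counts["O"], counts["S"])


def _covalent_hydrogen_partners(
    structure: ProteinStructure,
) -> dict[int, int]:
    """Map each H serial to the serial of its covalent heavy partner.

    Uses explicit bonds when the structure has them, otherwise the
    nearest heavy atom within 1.2 A.
    """
    partners: dict[int, int] = {}
    if structure.bonds:
        heavy = {a.serial for a in structure.atoms if a.is_heavy}
        for pair in structure.bonds:
            i, j = tuple(pair)
            for h, x in ((i, j), (j, i)):
                if structure.atom_by_serial(h).element == "H" and x in heavy:
                    partners[h] = x
    hydrogens = [a for a in structure.atoms if a.element == "H"]
    heavies = [a for a in structure.atoms if a.is_heavy]
    if not heavies:
        return partners
    hp = np.array([a.position for a in heavies])
    for h in hydrogens:
        if h.serial in partners:
            continue
        d = np.linalg.norm(hp - h.position, axis=1)
        k = int(np.argmin(d))
        if d[k] <= 1.2:
            partners[h.serial] = heavies[k].serial
    return partners


def detect_hydrogen_bonds(
    structure: ProteinStructure,
    distance_cutoff: float = HBOND_H_ACCEPTOR_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> dict[int, tuple[int, int]]:
    """Count hydrogen bonds per heavy atom, split by acceptor/donor role.

    A donor-H...acceptor triple is accepted when the donor and acceptor
    are N or O in *different* residues, the H...acceptor distance is
    ``<= distance_cutoff`` and the donor-H-acceptor angle is
    ``>= angle_cutoff``.  Returns serial -> (n_as_acceptor, n_as_donor);
    atoms with no role have entry (0, 0).  Structures without hydrogens
    yield all-zero counts.
    """
    counts: dict[int, list[int]] = {a.serial: [0, 0] for a in structure.atoms}
    partners = _covalent_hydrogen_partners(structure)
    acceptors = [a for a in structure.atoms if a.element in ("N", "O")]
    if acceptors:
        acc_pos = np.array([a.position for a in acceptors])
    cos_cut = np.cos(np.deg2rad(angle_cutoff))
    for h in structure.atoms:
        if h.element != "H" or h.serial not in partners:
            continue
        donor = structure.atom_by_serial(partners[h.serial])
        if donor.element not in ("N", "O"):
            continue
        if not acceptors:
            continue
        dist = np.linalg.norm(acc_pos - h.position, axis=1)
        for idx in np.nonzero(dist <= distance_cutoff)[0]:
            acc = acceptors[int(idx)]
            if acc.serial == donor.serial:
                continue
            if (
                acc.chain_id == donor.chain_id
                and acc.residue_seq == donor.residue_seq
            ):
                continue  # intra-residue pairs excluded
            v1 = donor.position - h.position
            v2 = acc.position - h.position
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
            if float(v1 @ v2) / (n1 * n2) <= cos_cut:
                counts[acc.serial][0] += 1
                counts[donor.serial][1] += 1
    return {s: (c[0], c[1]) for s, c in counts.items()}


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _residue_orientations(structure: ProteinStructure) -> dict[int, np.ndarray]:
    """Per-atom quadrature orientation from each residue's local frame.

    Returns serial -> 3x3 matrix mapping quadrature directions into the
    global frame.  Residues lacking valid CA/C/O anchors fall back to the
    identity.  Because the frames co-rotate with the structure, the SASA
    quadrature becomes exactly pose-covariant instead of merely
    approximately so.
    """
    from .local_frame import DegenerateGeometryError, build_local_frame

    orientations: dict[int, np.ndarray] = {}
    for _key, atoms in structure.residues().items():
        by_name = {a.atom_name: a for a in atoms}
        M = np.eye(3)
        if {"CA", "C", "O"} <= set(by_name):
            try:
                frame = build_local_frame(
                    by_name["CA"].position, by_name["C"].position,
                    by_name["O"].position,
                )
                M = frame.rotation  # rows are the local axes
            except DegenerateGeometryError:
                pass
        for a in atoms:
            orientations[a.serial] = M
    return orientations


def compute_sasa(
    structure: ProteinStructure,
    n_points: int = 960,
    probe: float = SASA_PROBE_RADIUS,
    orient_by_residue: bool = True,
) -> dict[int, float]:
    """Shrake-Rupley solvent accessible surface area per atom (A^2).

    For each atom, ``n_points`` quasi-uniform points are placed on its
    solvent-expanded sphere (r_vdw + probe); the accessible fraction is
    the share of points not inside any other atom's expanded sphere,
    times the sphere area 4*pi*(r_vdw + probe)^2.  The golden-spiral
    point set is deterministic, so results are bit-reproducible; with
    ``orient_by_residue`` the point set is expressed in each residue's
    local frame, making the estimate exactly invariant under rigid motion
    of the whole structure.
    """
    if n_points < 16:
        raise ValueError("n_points < 16: quadrature too coarse for SASA")
    atoms = structure.atoms
    pos = structure.positions()
    radii = np.array(
        [VDW_RADII.get(a.element, VDW_RADIUS_DEFAULT) for a in atoms]
    )
    expanded = radii + probe
    unit_points = _golden_spiral_points(n_points)
    orientations = (
        _residue_orientations(structure) if orient_by_residue else None
    )
    out: dict[int, float] = {}
    for i, atom in enumerate(atoms):
        dirs = (
            unit_points @ orientations[atom.serial]
            if orientations is not None
            else unit_points
        )
        sphere = atom.position + expanded[i] * dirs
        # candidate occluders: expanded spheres that can reach this one
        d = np.linalg.norm(pos - atom.position, axis=1)
        cand = np.nonzero((d < expanded[i] + expanded) & (d > 0))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in cand:
            dj = np.linalg.norm(sphere - pos[j], axis=1)
            accessible &= dj >= expanded[j]
        frac = accessible.mean()
        out[atom.serial] = float(
            frac * 4.0 * np.pi * expanded[i] ** 2
        )
    return out
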