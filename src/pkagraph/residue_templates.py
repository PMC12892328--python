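"""Ideal-geometry amino-acid templates.

Each template lists the atoms of one residue (name, element, backbone
flag, position) together with its covalent bonds as atom-name pairs.
Positions are expressed directly in the residue's own local frame:
C-alpha at the origin, the carbonyl C at (1.53, 0, 0) on the +X axis,
and the carbonyl O in the XY-plane at a 121 deg Calpha-C-O angle, so the
whole carbonyl group is exactly planar (local Z of O is exactly 0).

Covered types: the four ionizable residues (ASP, GLU, HIS, LYS) and two
spacers (GLY, ALA).  Geometry uses standard amino-acid stereochemistry
(bond lengths 1.0-1.55 A, tetrahedral / trigonal angles); side-chain
conformations are one fixed, clash-free rotamer per type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResidueTemplate", "RESIDUE_TEMPLATES", "SPACER_RESIDUES",
           "template_bond_serial_pairs"]


@dataclass(frozen=True)
class ResidueTemplate:
    residue_name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    backbone_flags: tuple[bool, ...]
    positions: np.ndarray  # (n_atoms, 3), local-frame Angstrom
    bonds: tuple[tuple[str, str], ...]  # intra-residue, by atom name

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def index_of(self, atom_name: str) -> int:
        return self.atom_names.index(atom_name)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rot_in_plane(v: np.ndarray, normal: np.ndarray, deg: float) -> np.ndarray:
    """Rotate v by deg around the (unit) normal (Rodrigues, v ⟂ normal)."""
    a = np.deg2rad(deg)
    return v * np.cos(a) + np.cross(normal, v) * np.sin(a)


def _methylene_h(center, prev_pos, next_pos, bond=1.09):
    """Two H positions on an sp3 CH2 given its two heavy neighbors."""
    a = _unit(prev_pos - center)
    b = _unit(next_pos - center)
    bisector = -_unit(a + b)
    n = _unit(np.cross(a, b))
    half = np.deg2rad(54.0)
    h1 = center + bond * (bisector * np.cos(half) + n * np.sin(half))
    h2 = center + bond * (bisector * np.cos(half) - n * np.sin(half))
    return h1, h2


def _three_fold_h(center, stem_dir, w, q, bond=1.01):
    """Three H positions around a terminal sp3 atom (methyl / ammonium)."""
    cone = np.deg2rad(70.5)
    out = []
    for k in range(3):
        theta = np.deg2rad(90.0 + 120.0 * k)
        d = stem_dir * np.cos(cone) + np.sin(cone) * (
            np.cos(theta) * w + np.sin(theta) * q
        )
        out.append(center + bond * d)
    return out


def _build_templates() -> dict[str, ResidueTemplate]:
    # --- shared backbone geometry (local frame) ---
    ca = np.zeros(3)
    c = np.array([1.53, 0.0, 0.0])
    ang_o = np.deg2rad(180.0 - 121.0)  # Calpha-C-O angle 121 deg
    o = c + 1.23 * np.array([np.cos(ang_o), np.sin(ang_o), 0.0])
    ang_n = np.deg2rad(110.0)  # N-Calpha-C angle
    n = 1.46 * np.array([np.cos(ang_n), -np.sin(ang_n), 0.0])
    h = n * (1.0 + 1.01 / 1.46)  # amide H, radially out from Calpha
    # tetrahedral directions at Calpha for HA and CB
    d_up = np.array([-0.331, 0.473, 0.817])
    d_up = _unit(d_up)
    d_dn = d_up * np.array([1.0, 1.0, -1.0])
    ha = 1.09 * d_dn
    cb = 1.53 * d_up

    u = d_up  # side-chain stem direction
    w = _unit(np.cross(u, np.array([1.0, 0.0, 0.0])))
    q = _unit(np.cross(u, w))
    phi = np.deg2rad(35.0)
    d1 = np.cos(phi) * u + np.sin(phi) * w  # zig
    d2 = np.cos(phi) * u - np.sin(phi) * w  # zag

    bb_atoms = [
        ("N", "N", True, n),
        ("CA", "C", True, ca),
        ("C", "C", True, c),
        ("O", "O", True, o),
        ("H", "H", True, h),
        ("HA", "H", True, ha),  # backbone H: covalent partner is CA
    ]
    bb_bonds = [("N", "CA"), ("CA", "C"), ("C", "O"), ("N", "H"), ("CA", "HA")]

    def make(name, extra_atoms, extra_bonds, ha_name="HA"):
        atoms = [a for a in bb_atoms]
        if ha_name != "HA":
            atoms = [
                (ha_name, el, bbf, pos) if nm == "HA" else (nm, el, bbf, pos)
                for nm, el, bbf, pos in atoms
            ]
        atoms += extra_atoms
        bonds = [
            (a, b if b != "HA" else ha_name)
            for a, b in ((x, y if y != "HA" else ha_name) for x, y in bb_bonds)
        ] + extra_bonds
        return ResidueTemplate(
            residue_name=name,
            atom_names=tuple(a[0] for a in atoms),
            elements=tuple(a[1] for a in atoms),
            backbone_flags=tuple(a[2] for a in atoms),
            positions=np.array([a[3] for a in atoms], dtype=float),
            bonds=tuple(bonds),
        )

    templates: dict[str, ResidueTemplate] = {}

    # --- GLY: second alpha hydrogen where CB would sit ---
    templates["GLY"] = make(
        "GLY",
        [("HA3", "H", True, 1.09 * d_up)],
        [("CA", "HA3")],
        ha_name="HA2",
    )

    # --- ALA ---
    hb = _three_fold_h(cb, u, w, q, bond=1.09)
    templates["ALA"] = make(
        "ALA",
        [("CB", "C", False, cb)]
        + [(f"HB{k + 1}", "H", False, p) for k, p in enumerate(hb)],
        [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")],
    )

    # --- ASP: CB-CG-(OD1, OD2) carboxylate ---
    cg = cb + 1.52 * d1
    normal = _unit(np.cross(u, w))
    od1 = cg + 1.25 * _rot_in_plane(-d1, normal, 117.0)
    od2 = cg + 1.25 * _rot_in_plane(-d1, normal, -117.0)
    hb2, hb3 = _methylene_h(cb, ca, cg)
    templates["ASP"] = make(
        "ASP",
        [
            ("CB", "C", False, cb),
            ("CG", "C", False, cg),
            ("OD1", "O", False, od1),
            ("OD2", "O", False, od2),
            ("HB2", "H", False, hb2),
            ("HB3", "H", False, hb3),
        ],
        [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2"),
         ("CB", "HB2"), ("CB", "HB3")],
    )

    # --- GLU: CB-CG-CD-(OE1, OE2) ---
    cd = cg + 1.52 * d2
    oe1 = cd + 1.25 * _rot_in_plane(-d2, normal, 117.0)
    oe2 = cd + 1.25 * _rot_in_plane(-d2, normal, -117.0)
    hg2, hg3 = _methylene_h(cg, cb, cd)
    templates["GLU"] = make(
        "GLU",
        [
            ("CB", "C", False, cb),
            ("CG", "C", False, cg),
            ("CD", "C", False, cd),
            ("OE1", "O", False, oe1),
            ("OE2", "O", False, oe2),
            ("HB2", "H", False, hb2),
            ("HB3", "H", False, hb3),
            ("HG2", "H", False, hg2),
            ("HG3", "H", False, hg3),
        ],
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
         ("CD", "OE2"), ("CB", "HB2"), ("CB", "HB3"),
         ("CG", "HG2"), ("CG", "HG3")],
    )

    # --- HIS: planar imidazole ring off CG (neutral, H on ND1) ---
    cg_h = cb + 1.50 * d1
    ring_r = 1.37 / (2.0 * np.sin(np.pi / 5.0))  # pentagon circumradius
    center = cg_h + ring_r * d1
    ring_names = ["CG", "ND1", "CE1", "NE2", "CD2"]
    ring_elems = ["C", "N", "C", "N", "C"]
    ring_pos = []
    for k in range(5):
        theta = 180.0 + 72.0 * k
        ring_pos.append(
            center
            + ring_r
            * _rot_in_plane(d1, normal, theta)
        )
    ring_pos[0] = cg_h  # exact by construction (theta=180 gives -d1)
    ring_h = {}
    for nm, p in zip(("ND1", "CE1", "NE2", "CD2"), ring_pos[1:]):
        if nm == "NE2":
            continue  # neutral tautomer: no H on NE2
        ring_h["H" + nm[1:]] = p + 1.02 * _unit(p - center)
    hb2h, hb3h = _methylene_h(cb, ca, cg_h)
    templates["HIS"] = make(
        "HIS",
        [("CB", "C", False, cb)]
        + [
            (nm, el, False, p)
            for nm, el, p in zip(ring_names[1:], ring_elems[1:], ring_pos[1:])
        ]
        + [("CG", "C", False, cg_h)]
        + [(nm, "H", False, p) for nm, p in ring_h.items()]
        + [("HB2", "H", False, hb2h), ("HB3", "H", False, hb3h)],
        [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"),
         ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG"),
         ("ND1", "HD1"), ("CE1", "HE1"), ("CD2", "HD2"),
         ("CB", "HB2"), ("CB", "HB3")],
    )

    # --- LYS: CB-CG-CD-CE-NZ with ammonium hydrogens ---
    cg_l = cb + 1.52 * d1
    cd_l = cg_l + 1.52 * d2
    ce_l = cd_l + 1.52 * d1
    nz_l = ce_l + 1.49 * d2
    hk = {}
    hk["HB2"], hk["HB3"] = _methylene_h(cb, ca, cg_l)
    hk["HG2"], hk["HG3"] = _methylene_h(cg_l, cb, cd_l)
    hk["HD2"], hk["HD3"] = _methylene_h(cd_l, cg_l, ce_l)
    hk["HE2"], hk["HE3"] = _methylene_h(ce_l, cd_l, nz_l)
    for k, p in enumerate(_three_fold_h(nz_l, d2, w, q, bond=1.01)):
        hk[f"HZ{k + 1}"] = p
    templates["LYS"] = make(
        "LYS",
        [
            ("CB", "C", False, cb),
            ("CG", "C", False, cg_l),
            ("CD", "C", False, cd_l),
            ("CE", "C", False, ce_l),
            ("NZ", "N", False, nz_l),
        ]
        + [(nm, "H", False, p) for nm, p in hk.items()],
        [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
         ("CE", "NZ"),
         ("CB", "HB2"), ("CB", "HB3"), ("CG", "HG2"), ("CG", "HG3"),
         ("CD", "HD2"), ("CD", "HD3"), ("CE", "HE2"), ("CE", "HE3"),
         ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    )

    return templates


RESIDUE_TEMPLATES: dict[str, ResidueTemplate] = _build_templates()

SPACER_RESIDUES: tuple[str, ...] = ("GLY", "ALA")


def template_bond_serial_pairs(
    residue_name: str, name_to_serial: dict[str, int]
) -> set[frozenset[int]]:
    """Translate a residue's template bonds into serial pairs.

    Bonds whose atoms are absent from the mapping are skipped (partial
    residues).  Raises KeyError for an unknown residue type.
    """
    tmpl = RESIDUE_TEMPLATES[residue_name]
    pairs: set[frozenset[int]] = set()
    for a, b in tmpl.bonds:
        if a in name_to_serial and b in name_to_serial:
            pairs.add(frozenset((name_to_serial[a], name_to_serial[b])))
    return pairs
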