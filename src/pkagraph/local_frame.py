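"""Universal local coordinate frame for a target residue.

The frame exploits the planarity of the peptide carbonyl group: the
origin sits on the target residue's C-alpha, the X-axis points along
C-alpha -> carbonyl C, the Z-axis is normal to the plane spanned by the
X-axis and the carbonyl C=O bond, and Y completes a right-handed
orthonormal triad (placing the carbonyl O at positive local Y).
Expressing atom coordinates — and dipole vectors — in this frame makes
the downstream feature representation invariant to the protein's global
pose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LocalFrame", "DegenerateGeometryError", "build_local_frame",
           "to_local", "rotate_vector"]

_MIN_BOND = 0.5  # Angstrom; below this the Calpha-C anchors are coincident
_MIN_SINE = 1e-6  # collinearity guard for the carbonyl O


class DegenerateGeometryError(ValueError):
    """Anchor atoms are coincident or collinear; no frame exists."""


@dataclass(frozen=True)
class LocalFrame:
    """Origin (C-alpha position) plus right-handed orthonormal axes."""

    origin: np.ndarray
    e_x: np.ndarray
    e_y: np.ndarray
    e_z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "e_x", "e_y", "e_z"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        for name in ("e_x", "e_y", "e_z"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not unit length")
        ex, ey, ez = self.e_x, self.e_y, self.e_z
        if max(abs(ex @ ey), abs(ex @ ez), abs(ey @ ez)) > 1e-9:
            raise ValueError("axes are not orthogonal")
        if abs(float(ex @ np.cross(ey, ez)) - 1.0) > 1e-9:
            raise ValueError("axes are not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as rows: maps global to local vectors."""
        return np.stack([self.e_x, self.e_y, self.e_z])


def build_local_frame(
    ca: np.ndarray, carbonyl_c: np.ndarray, carbonyl_o: np.ndarray
) -> LocalFrame:
    """Construct the frame from the C-alpha, carbonyl C and carbonyl O.

    e_x = unit(C - Ca); e_z = unit(e_x x unit(O - C)); e_y = e_z x e_x.
    The sign convention places the carbonyl O at positive local Y.
    """
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(carbonyl_c, dtype=float)
    o = np.asarray(carbonyl_o, dtype=float)

    x_vec = c - ca
    x_norm = np.linalg.norm(x_vec)
    if x_norm <= _MIN_BOND:
        raise DegenerateGeometryError(
            f"C-alpha and carbonyl C are {x_norm:.3f} A apart (< {_MIN_BOND} A)"
        )
    e_x = x_vec / x_norm

    co = o - c
    co_norm = np.linalg.norm(co)
    if co_norm < 1e-12:
        raise DegenerateGeometryError("carbonyl C and O coincide")
    co_unit = co / co_norm

    z_vec = np.cross(e_x, co_unit)
    sine = np.linalg.norm(z_vec)
    if sine <= _MIN_SINE:
        raise DegenerateGeometryError(
            "carbonyl O is collinear with the C-alpha -> C axis"
        )
    e_z = z_vec / sine
    e_y = np.cross(e_z, e_x)
    return LocalFrame(origin=ca, e_x=e_x, e_y=e_y, e_z=e_z)


def to_local(frame: LocalFrame, points: np.ndarray) -> np.ndarray:
    """Transform points (3,) or (N, 3) into the local frame.

    output_i = R @ (point_i - origin), with R the axes stacked as rows.
    An isometry: pairwise distances are preserved.
    """
    pts = np.asarray(points, dtype=float)
    return (pts - frame.origin) @ frame.rotation.T


def rotate_vector(frame: LocalFrame, v: np.ndarray) -> np.ndarray:
    """Rotate a free vector (e.g. a dipole moment) into the local frame.

    Rotation only — no origin subtraction; the norm is preserved.
    Accepts (3,) or (N, 3).
    """
    return np.asarray(v, dtype=float) @ frame.rotation.T
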