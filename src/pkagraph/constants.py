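"""Physical constants and element tables shared across the package.

All coordinates are in Angstrom, dipole moments in Debye, areas in
Angstrom^2; there is no internal unit switching.
"""

# 1 Debye in SI units (Coulomb-meter).
DEBYE_IN_COULOMB_METER: float = 3.33564e-30

# van der Waals radii (Angstrom) used by the Shrake-Rupley SASA estimate.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
VDW_RADIUS_DEFAULT: float = 1.70  # fallback for ions / unusual elements

# Water-probe radius (Angstrom) for solvent accessible surface area.
SASA_PROBE_RADIUS: float = 1.4

# Reference (model-compound) pKa values of the four ionizable residue
# types handled by this package.  Used by the null model and by the
# pKa-shift metrics.
REFERENCE_PKA: dict[str, float] = {
    "ASP": 3.7,
    "GLU": 4.2,
    "HIS": 6.5,
    "LYS": 10.4,
}

#: The ionizable residue types a graph can be built for, in the fixed
#: alphabetical order used by the residue one-hot feature block.
IONIZABLE_RESIDUES: tuple[str, ...] = ("ASP", "GLU", "HIS", "LYS")

# Backbone heavy-atom names (standard PDB nomenclature).
BACKBONE_HEAVY_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

# Residue names treated as water and dropped on PDB ingest.
WATER_RESIDUES: frozenset[str] = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3"})

# Distance cutoffs (Angstrom) for the covalent-bond distance fallback.
HEAVY_HEAVY_BOND_CUTOFF: float = 1.9
X_H_BOND_CUTOFF: float = 1.2
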