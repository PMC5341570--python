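"""Element tables and residue-name sets shared by the analysis modules.

Internal length unit is nanometres everywhere; Angstrom appears only at file
boundaries (PDB stores Angstrom).
"""

from __future__ import annotations

import warnings

#: Å per nm, applied only when reading/writing PDB files.
ANGSTROM_PER_NM = 10.0

#: Standard atomic masses (u).  Unknown elements fall back to 12.0 with a warning.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845, "MN": 54.938, "CU": 63.546,
}

DEFAULT_MASS = 12.0

#: Bondi-style van der Waals radii (nm) used for solvent-accessible surface area.
VDW_RADII_NM: dict[str, float] = {
    "H": 0.120, "D": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "SE": 0.190, "F": 0.147, "CL": 0.175,
    "BR": 0.185, "I": 0.198,
}

#: Fallback vdW radius (nm) for elements missing from the table.
DEFAULT_VDW_RADIUS_NM = 0.152

#: The 20 standard amino acids plus common variants seen in deposited structures.
STANDARD_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # variants / alternate protonation names
    "MSE", "SEC", "PYL", "CYX", "HID", "HIE", "HIP", "HSD", "HSE", "HSP",
})

#: Residue names recognised as water.
WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "H2O", "DOD"})

#: Backbone atom names (protein).
BACKBONE_ATOMS = ("N", "CA", "C", "O")

# geometric bond-perception cutoffs, nm
PEPTIDE_BOND_CUTOFF_NM = 0.19
HEAVY_HEAVY_BOND_CUTOFF_NM = 0.19
HYDROGEN_BOND_LENGTH_CUTOFF_NM = 0.12
DISULFIDE_CUTOFF_NM = 0.25

#: Amide N-H bond length used when hydrogens must be constructed (nm).
AMIDE_NH_LENGTH_NM = 0.101


def mass_of(element: str) -> float:
    """Atomic mass of ``element`` (u); unknown elements get 12.0 with a warning."""
    m = ATOMIC_MASSES.get(element.upper())
    if m is None:
        warnings.warn(f"unknown element {element!r}: using default mass {DEFAULT_MASS}")
        return DEFAULT_MASS
    return m


def vdw_radius_of(element: str) -> float:
    """Van der Waals radius of ``element`` in nm, with a warned default."""
    r = VDW_RADII_NM.get(element.upper())
    if r is None:
        warnings.warn(
            f"unknown element {element!r}: using default vdW radius "
            f"{DEFAULT_VDW_RADIUS_NM} nm"
        )
        return DEFAULT_VDW_RADIUS_NM
    return r
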