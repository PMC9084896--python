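"""Chemical reference tables: chi-angle atoms, gamma atoms, donors/acceptors,
van der Waals radii, and theoretical maximum accessible surface areas."""

from __future__ import annotations

# chi dihedral atom quadruples per residue type, in chi1..chiN order.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# (residue, chi index 1-based) whose terminal chi is 2-fold symmetric;
# the angle is reported modulo 180 degrees.
SYMMETRIC_CHI: set[tuple[str, int]] = {
    ("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2),
}

# First gamma-position heavy atom defining the chi1 bond direction
# (Cbeta -> gamma).  Val/Ile use CG1 (rotalyze chi1 convention).
GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG",
    "TYR": "CG", "VAL": "CG1",
}

# Residues for which the chi1-based angular order parameter is undefined.
NO_S2_RESIDUES = {"GLY", "PRO"}

# Side-chain hydrogen-bond donor heavy atoms (must carry an H) per residue.
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "CYS": {"SG"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

# Side-chain hydrogen-bond acceptor atoms per residue.
SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

# Backbone donor/acceptor atoms (all amino acids; Pro N carries no H).
BACKBONE_DONOR = "N"
BACKBONE_ACCEPTORS = {"O", "OXT"}

# van der Waals radii in Angstrom by element.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98,
}

# Theoretical maximum accessible surface area per residue type (A^2),
# Tien et al. 2013 theoretical values; denominators for relative ASA.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# Common crystallographic additives excluded when classifying a structure
# as ligand-bound, plus the synthetic occlusion-shell residue code.
DEFAULT_ADDITIVES: set[str] = {
    "HOH", "GOL", "EDO", "PEG", "PGE", "PG4", "SO4", "PO4", "ACT", "DMS",
    "MPD", "TRS", "EPE", "MES", "FMT", "IMD", "BME", "CIT", "TLA", "NO3",
    "CAC", "IPA", "ACY", "CAG",
}
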