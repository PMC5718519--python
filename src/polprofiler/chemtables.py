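"""Chemical lookup tables used across the package.

All hydrogen-bond chemistry here is heavy-atom only: donor/acceptor roles are
assigned to N/O/S atoms of the standard amino acids, the four
deoxyribonucleotides, water and triphosphate ligands.  Base-edge (minor
groove / major groove / Watson-Crick) assignments follow the standard
presentation of base atoms to the two grooves and are kept in one place so
they can be audited at a glance.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# residue-name tables for entity classification
# ---------------------------------------------------------------------------

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "DU", "DOC", "DDC", "DDG"}

WATER_RESIDUES = {"HOH", "WAT", "DOD"}

METAL_RESIDUES = {"MG", "MN", "CA", "NA", "K", "ZN", "FE"}

# common triphosphate ligand codes; atom-content heuristics catch the rest
DNTP_RESIDUES = {"DTP", "ATP", "GTP", "CTP", "TTP", "UTP", "DGT", "DCP",
                 "DAD", "TTP", "D3T", "2DT", "DCT"}

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

# ---------------------------------------------------------------------------
# donor / acceptor roles (heavy atoms; value in {"donor", "acceptor", "both"})
# ---------------------------------------------------------------------------

# backbone of every amino acid
_BB = {"N": "donor", "O": "acceptor", "OXT": "acceptor"}

_SIDECHAIN_ROLES = {
    "ALA": {},
    "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
    "ASN": {"OD1": "acceptor", "ND2": "donor"},
    "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
    "CYS": {"SG": "both"},
    "GLN": {"OE1": "acceptor", "NE2": "donor"},
    "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
    "GLY": {},
    "HIS": {"ND1": "both", "NE2": "both"},
    "ILE": {},
    "LEU": {},
    "LYS": {"NZ": "donor"},
    "MET": {"SD": "acceptor"},
    "MSE": {},
    "PHE": {},
    "PRO": {},
    "SER": {"OG": "both"},
    "THR": {"OG1": "both"},
    "TRP": {"NE1": "donor"},
    "TYR": {"OH": "both"},
    "VAL": {},
}

# deoxyribonucleotide roles: sugar-phosphate oxygens are acceptors, base
# atoms follow Watson-Crick chemistry (exocyclic amines donate, carbonyls
# and ring nitrogens accept)
_SUGAR_PHOSPHATE_ROLES = {
    "P": None,  # phosphorus itself is not an H-bond partner
    "OP1": "acceptor", "OP2": "acceptor", "OP3": "acceptor",
    "O5'": "acceptor", "O3'": "both", "O4'": "acceptor",
}

_BASE_ROLES = {
    "DA": {"N1": "acceptor", "N3": "acceptor", "N6": "donor", "N7": "acceptor",
           "N9": None},
    "DG": {"N1": "donor", "N2": "donor", "N3": "acceptor", "N7": "acceptor",
           "O6": "acceptor", "N9": None},
    "DC": {"N1": None, "N3": "acceptor", "N4": "donor", "O2": "acceptor"},
    "DT": {"N1": None, "N3": "donor", "O2": "acceptor", "O4": "acceptor"},
}
_BASE_ROLES["DI"] = {"N1": "donor", "N3": "acceptor", "N7": "acceptor",
                     "O6": "acceptor", "N9": None}
_BASE_ROLES["DU"] = dict(_BASE_ROLES["DT"])
_BASE_ROLES["DOC"] = dict(_BASE_ROLES["DC"])
_BASE_ROLES["DDC"] = dict(_BASE_ROLES["DC"])
_BASE_ROLES["DDG"] = dict(_BASE_ROLES["DG"])

# triphosphate ligand (dATP-like): alpha/beta/gamma phosphate oxygens accept,
# adenine base as in DA, sugar oxygens as in DNA (no O3'-H modelled: "both")
_DNTP_ROLES = {
    "O1A": "acceptor", "O2A": "acceptor", "O3A": "acceptor",
    "O1B": "acceptor", "O2B": "acceptor", "O3B": "acceptor",
    "O1G": "acceptor", "O2G": "acceptor", "O3G": "acceptor",
    "O5'": "acceptor", "O4'": "acceptor", "O3'": "both",
    "N1": "acceptor", "N3": "acceptor", "N6": "donor", "N7": "acceptor",
    # pyrimidine triphosphates
    "O2": "acceptor", "O4": "acceptor", "N4": "donor",
}

WATER_ROLES = {"O": "both", "OW": "both"}


def default_donor_acceptor_table() -> dict[str, dict[str, str]]:
    """Per-residue-name atom -> role {donor, acceptor, both} table."""
    table: dict[str, dict[str, str]] = {}
    for aa, side in _SIDECHAIN_ROLES.items():
        table[aa] = dict(_BB) | side
    for res, base in _BASE_ROLES.items():
        roles = {k: v for k, v in (_SUGAR_PHOSPHATE_ROLES | base).items()
                 if v is not None}
        table[res] = roles
    for res in DNTP_RESIDUES:
        table[res] = dict(_DNTP_ROLES)
    for res in WATER_RESIDUES:
        table[res] = dict(WATER_ROLES)
    return table


def roles_compatible(role_a: str, role_b: str) -> bool:
    """True if one side can donate while the other accepts."""
    da = role_a in ("donor", "both")
    ab = role_b in ("acceptor", "both")
    ad = role_b in ("donor", "both")
    ba = role_a in ("acceptor", "both")
    return (da and ab) or (ad and ba)


# ---------------------------------------------------------------------------
# DNA moiety tables (groove edges etc.)
# ---------------------------------------------------------------------------

PHOSPHATE_BACKBONE_ATOMS = {"P", "OP1", "OP2", "OP3", "O3'", "O5'"}
SUGAR_RING_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'"}

# base atoms by groove edge; anything on the ring not on an edge is "base"
PURINE_MINOR = {"N3", "C2", "N2"}
PURINE_MAJOR = {"N7", "O6", "N6", "C6", "C8"}
PURINE_WC = {"N1"}
PYRIMIDINE_MINOR = {"O2"}
PYRIMIDINE_MAJOR = {"C5", "C7", "C5M", "O4", "N4", "C6"}
PYRIMIDINE_WC = {"N3"}

PURINE_RESIDUES = {"DA", "DG", "DI", "DDG"}
PYRIMIDINE_RESIDUES = {"DC", "DT", "DU", "DOC", "DDC"}

# which bases purine-type triphosphates carry (by residue code)
PURINE_DNTP = {"DTP", "ATP", "GTP", "DGT", "DAD"}

DNTP_ALPHA = {"PA", "O1A", "O2A", "O3A", "O5'"}
DNTP_BETA = {"PB", "O1B", "O2B", "O3B"}
DNTP_GAMMA = {"PG", "O1G", "O2G", "O3G"}

TRIPHOSPHATE_ATOMS = {"PA", "PB", "PG"} | {
    f"O{i}{g}" for i in (1, 2, 3) for g in ("A", "B", "G")
}

# aromatic side-chain ring atoms, for ring-sugar stacking detection
AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# ---------------------------------------------------------------------------
# van der Waals radii (Bondi), Angstrom
# ---------------------------------------------------------------------------

BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "MN": 1.73, "CA": 1.73, "NA": 2.27, "K": 2.75,
    "ZN": 1.39, "FE": 1.73,
}
DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return BONDI_RADII.get(element.upper(), DEFAULT_VDW)
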