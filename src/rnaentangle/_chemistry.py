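"""Reference chemistry tables for ribonucleotides.

Atom-name sets follow PDB v3 nomenclature.  The tables are used to decide
whether a chain is RNA, which atoms of a modified residue are "surplus"
relative to its parent ribonucleotide, and which atoms span the nucleobase
ring (for center-of-mass pseudoatoms and base-plane normals).
"""

from __future__ import annotations

STANDARD_RIBONUCLEOTIDES = {"A", "C", "G", "U"}

# Ribose + phosphate backbone atoms shared by all ribonucleotides.
BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}

# Base heavy atoms (ring + exocyclic) per parent residue.
BASE_ATOMS = {
    "A": {"N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"},
    "G": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"},
    "C": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"},
    "U": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"},
}

# Ring atoms only — used for the base center-of-mass pseudoatom and for the
# base-plane normal in pair detection.
RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

#: glycosidic nitrogen per parent type
GLYCOSIDIC_ATOM = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: Watson-Crick edge atom used as the primary H-bond gate in pair detection
WC_EDGE_ATOM = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}

# Common modified ribonucleotides mapped to their parent base.  Unmapped
# residues that still carry a ribose (O2') and a base ring are kept as
# generic nucleotides.
MODIFIED_PARENT = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "OMU": "U", "UR3": "U",
    "3MU": "U", "70U": "U", "DHU": "U",
    "1MA": "A", "2MA": "A", "MA6": "A", "6MA": "A", "A2M": "A", "RIA": "A",
    "MIA": "A", "T6A": "A", "6IA": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C", "CCC": "C", "5IC": "C",
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "YG": "G",
    "YYG": "G", "QUO": "G", "G7M": "G", "GTP": "G", "GDP": "G",
    "I": "G", "IU": "U",
}

# Residue names that are never RNA (used to shortcut chain classification).
WATER_NAMES = {"HOH", "DOD", "WAT"}
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "SEC", "PYL", "MSE",
}
DEOXYRIBONUCLEOTIDES = {"DA", "DC", "DG", "DT", "DU", "DI"}

# Canonical pair types and the donor/acceptor atom pairs checked by the
# geometric detector.  The first entry per type is the primary WC-edge gate.
CANONICAL_PAIRS = {
    frozenset(("A", "U")): "WC-AU",
    frozenset(("G", "C")): "WC-GC",
    frozenset(("G", "U")): "wobble-GU",
}

HBOND_ATOMS = {
    "WC-AU": [("N1", "N3"), ("N6", "O4")],      # A first, U second
    "WC-GC": [("N1", "N3"), ("O6", "N4"), ("N2", "O2")],  # G first, C second
    "wobble-GU": [("N1", "O2"), ("O6", "N3")],  # G first, U second
}


def allowed_atoms(parent: str) -> set[str]:
    """Full allowed heavy-atom set for a residue mapped to ``parent``."""
    return BACKBONE_ATOMS | BASE_ATOMS[parent]


def parent_of(res_name: str) -> str | None:
    """Parent A/C/G/U for a residue name, or None if unmapped."""
    if res_name in STANDARD_RIBONUCLEOTIDES:
        return res_name
    return MODIFIED_PARENT.get(res_name)
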