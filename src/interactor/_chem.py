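"""Static chemistry tables: residue codes, atom templates, radii and scales.

All per-residue tables are keyed by one-letter code over the 26-symbol
alphabet (20 standard residues, U = selenocysteine, O = pyrrolysine,
J = N-methylvaline, plus the B/Z/X ambiguity codes).  Atom-name templates
follow PDB v3 naming.
"""

from __future__ import annotations

# 26-symbol residue alphabet, in the fixed column order used everywhere.
ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# 3-letter -> 1-letter, standard residues plus supported rare residues.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # rare residues retained as first-class sequence symbols
    "SEC": "U",   # selenocysteine
    "PYL": "O",   # pyrrolysine
    "MVA": "J",   # N-methylvaline (no official letter; J is the spare symbol)
    "MSE": "M",   # selenomethionine, conventionally folded into Met
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Bondi-style van der Waals radii, Angstrom.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

# Single-bond covalent radii, Angstrom (used by distance-based bond inference).
COVALENT_RADII = {
    "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "H": 0.31, "P": 1.07,
    "SE": 1.20, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}
DEFAULT_COVALENT_RADIUS = 0.77

# Kyte-Doolittle hydropathy.  Ambiguity codes take the value shared by (or
# averaged over) their members; X is neutral by convention.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
    "U": 2.5, "O": -3.9, "J": 4.2, "B": -3.5, "Z": -3.5, "X": 0.0,
}

# Maximum accessible surface area in an extended Gly-X-Gly reference, A^2
# (theoretical values of Tien et al. 2013); rare/ambiguous symbols borrow
# from the chemically closest standard residue.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "U": 167.0, "O": 236.0, "J": 174.0, "B": 194.0, "Z": 224.0, "X": 197.0,
}

# Atomic solvation parameters, kcal/mol/A^2, Eisenberg-McLachlan style,
# keyed by atom solvation class (see atom_solvation_class below).
SOLVATION_PARAMS = {
    "C": 0.016,
    "N": -0.006,
    "O": -0.006,
    "O_charged": -0.024,
    "N_charged": -0.050,
    "S": 0.021,
    "SE": 0.021,
}

# Side-chain atoms carrying a formal charge at physiological pH.
CHARGED_O_ATOMS = {("D", "OD1"), ("D", "OD2"), ("E", "OE1"), ("E", "OE2")}
CHARGED_N_ATOMS = {("K", "NZ"), ("R", "NE"), ("R", "NH1"), ("R", "NH2"),
                   ("O", "NZ")}

# Heavy-atom hydrogen-bond donor / acceptor templates (atom names per
# one-letter residue code).  Backbone N donates (except proline) and
# backbone O/OXT accepts for every residue; listed here are side chains.
SIDECHAIN_DONORS = {
    "R": {"NE", "NH1", "NH2"},
    "N": {"ND2"},
    "Q": {"NE2"},
    "H": {"ND1", "NE2"},
    "K": {"NZ"},
    "S": {"OG"},
    "T": {"OG1"},
    "W": {"NE1"},
    "Y": {"OH"},
    "C": {"SG"},
    "U": {"SE"},
    "O": {"NZ"},
}
SIDECHAIN_ACCEPTORS = {
    "D": {"OD1", "OD2"},
    "E": {"OE1", "OE2"},
    "N": {"OD1"},
    "Q": {"OE1"},
    "H": {"ND1", "NE2"},
    "S": {"OG"},
    "T": {"OG1"},
    "Y": {"OH"},
}

# Side-chain atoms that are sp2 (aromatic rings, amide/guanidinium/
# carboxylate planes).  Backbone C, O and amide N are sp2 for all residues.
SIDECHAIN_SP2 = {
    "R": {"NE", "CZ", "NH1", "NH2"},
    "N": {"CG", "OD1", "ND2"},
    "D": {"CG", "OD1", "OD2"},
    "Q": {"CD", "OE1", "NE2"},
    "E": {"CD", "OE1", "OE2"},
    "H": {"CG", "ND1", "CD2", "CE1", "NE2"},
    "F": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "W": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "Y": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
}

# The 8 CPAASC side-chain classes as a mutually exclusive partition of the
# alphabet.  Histidine is grouped with the positively charged residues;
# tyrosine with the aromatics; ambiguity codes default to polar-uncharged.
CPAASC_CLASSES = {
    "aliphatic_apolar": set("AVLIJ"),
    "aromatic": set("FWY"),
    "polar_uncharged": set("NQBZX"),
    "positive": set("KRHO"),
    "negative": set("DE"),
    "sulfur_containing": set("CMU"),
    "hydroxyl_containing": set("ST"),
    "special": set("GP"),
}
CPAASC_ORDER = [
    "aliphatic_apolar", "aromatic", "polar_uncharged", "positive",
    "negative", "sulfur_containing", "hydroxyl_containing", "special",
]
CPAASC_FALLBACK = "polar_uncharged"


def residue_of(symbol: str) -> str:
    """Validate a one-letter symbol against the 26-letter alphabet."""
    if symbol not in ALPHABET:
        raise KeyError(f"unknown residue symbol {symbol!r}")
    return symbol


def element_from_atom_name(name: str) -> str | None:
    """Best-effort element from a PDB atom-name field."""
    stripped = name.strip()
    if not stripped:
        return None
    two = stripped[:2].upper()
    if two in ("SE", "CL", "BR", "FE", "ZN", "MG", "NA", "MN", "CA"):
        # 'CA' here only when the raw name is left-justified metal calcium;
        # protein CA carbons are handled by the single-letter branch below.
        if two == "CA" and name[:1] == " ":
            return "C"
        if two in VDW_RADII or two in ("FE", "ZN", "MG", "NA", "MN", "CA"):
            return two
    first = stripped[0].upper()
    if first.isdigit():  # e.g. 1HB2
        first = stripped[1].upper() if len(stripped) > 1 else ""
    if first in ("C", "N", "O", "S", "H", "P", "F", "I"):
        return first
    return None
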