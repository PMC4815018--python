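"""Chemical reference tables for protein analysis.

Everything downstream (residue categorisation, SASA radii, hydrogen-bond
donor/acceptor chemistry, salt-bridge charged groups, relative-accessibility
normalisation) reads from the fixed tables in this module, so conventions are
defined exactly once.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Amino-acid codes
# ---------------------------------------------------------------------------

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# Residue chemical categories
# ---------------------------------------------------------------------------
# Four-way scheme: charged side chains split by sign, uncharged split by
# polarity.  Histidine is counted as positively charged by default (it is a
# titratable base and participates in salt bridges); pass neutral_his=True
# for the alternative convention.

NON_POLAR = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
NEUTRAL_POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "GLY"}
CHARGED_POSITIVE = {"LYS", "ARG", "HIS"}
CHARGED_NEGATIVE = {"ASP", "GLU"}

CATEGORY_OTHER = "other"


def residue_category(name3: str, neutral_his: bool = False) -> str:
    """Chemical category of a residue by its 3-letter code.

    Returns one of ``non-polar``, ``neutral-polar``, ``charged-positive``,
    ``charged-negative`` or ``other`` for non-standard residues.
    """
    name3 = name3.upper()
    if neutral_his and name3 == "HIS":
        return "neutral-polar"
    if name3 in NON_POLAR:
        return "non-polar"
    if name3 in NEUTRAL_POLAR:
        return "neutral-polar"
    if name3 in CHARGED_POSITIVE:
        return "charged-positive"
    if name3 in CHARGED_NEGATIVE:
        return "charged-negative"
    return CATEGORY_OTHER


def merged_category(category: str) -> str:
    """Collapse the two charged categories into plain ``charged``.

    Used for three-way substitution reporting
    (non-polar / neutral-polar / charged).
    """
    if category in ("charged-positive", "charged-negative"):
        return "charged"
    return category


# ---------------------------------------------------------------------------
# Van der Waals radii (Bondi-type), Angstrom
# ---------------------------------------------------------------------------

VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


# ---------------------------------------------------------------------------
# Hydrogen-bond donor / acceptor template chemistry (heavy atoms)
# ---------------------------------------------------------------------------
# Backbone: every residue donates through the amide N (except proline, which
# has no amide hydrogen) and accepts through the carbonyl O.  Side chains
# follow standard protein chemistry; hydroxyls (Ser/Thr/Tyr) are both.

BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"

SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "CYS": ("SG",),
}

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

# ---------------------------------------------------------------------------
# Salt-bridge charged groups (heavy atoms)
# ---------------------------------------------------------------------------

NEGATIVE_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

POSITIVE_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# ---------------------------------------------------------------------------
# Theoretical maximum SASA per residue type (Gly-X-Gly, Angstrom^2)
# ---------------------------------------------------------------------------
# Theoretical maxima of Tien et al. (2013); used to normalise per-residue
# SASA to relative accessibility.

MAX_SASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
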