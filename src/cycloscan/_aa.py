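"""Amino-acid reference tables: names, charges, donors/acceptors, chi torsions."""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common heteroresidue aliases seen in deposited entries
    "MSE": "M", "SEC": "C", "PYL": "K",
}

ONE_TO_THREE = {v: k for k, v in list(THREE_TO_ONE.items())[:20]}

STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA3 = frozenset(ONE_TO_THREE.values())

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: sidechain formal charge at pH 7 (His neutral by convention here)
FORMAL_CHARGE = {
    "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": 0,
}

#: sidechain hydrogen-bond donor heavy atoms
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

#: sidechain hydrogen-bond acceptor heavy atoms
SIDECHAIN_ACCEPTORS = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: partial charges by (residue, atom); backbone handled separately
SIDECHAIN_PARTIAL_CHARGE = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): +1.0,
    ("ARG", "NH1"): +0.5, ("ARG", "NH2"): +0.5,
}

#: backbone partial charges (net zero per residue)
BACKBONE_PARTIAL_CHARGE = {"N": -0.35, "CA": +0.35, "C": +0.35, "O": -0.35}

#: chi torsion atom quadruples, in order chi1, chi2, ...
CHI_ATOMS = {
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
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [], "GLY": [], "PRO": [],
}

#: Lennard-Jones r_min/2 (Å) and well depth (kcal/mol) per element
LJ_RMIN_HALF = {"C": 1.90, "N": 1.80, "O": 1.70, "S": 2.00}
LJ_EPS = {"C": 0.10, "N": 0.14, "O": 0.16, "S": 0.20}


def one_letter(res_name: str) -> str:
    """Map a 3-letter residue name to one letter, 'X' if unknown."""
    return THREE_TO_ONE.get(res_name.upper(), "X")


def three_letter(code: str) -> str:
    try:
        return ONE_TO_THREE[code.upper()]
    except KeyError:
        raise ValueError(f"not a standard amino acid: {code!r}") from None
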