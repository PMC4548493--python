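"""Amino acid vocabulary shared across the package.

Twenty standard residues, three/one-letter code maps, a small table of
common modified residues with a standard parent, and the extended
Gly-X-Gly reference areas used to normalise solvent accessibility.
"""

from __future__ import annotations

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_AA: frozenset[str] = frozenset(THREE_TO_ONE.values())

# Modified residues mapped to their standard parent; anything not listed
# here (and not standard) is skipped with a warning when reading structures.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "CSO": "CYS",  # S-hydroxycysteine
    "HYP": "PRO",  # 4-hydroxyproline
    "KCX": "LYS",  # carboxylysine
    "MLY": "LYS",  # N-dimethyllysine
    "PCA": "GLU",  # pyroglutamate
}

# Reference solvent-accessible areas (A^2) of residue X in an extended
# Gly-X-Gly tripeptide (phi = psi = 180 deg), theoretical values of
# Tien et al. 2013.  Users may substitute their own table; rSASA values
# shift by a few percent between published tables.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def one_letter(code: str) -> str:
    """Normalise a one- or three-letter amino acid code to one-letter.

    Raises KeyError for anything that is not one of the 20 standard
    residues (modified residues must be mapped upstream).
    """
    code = code.strip().upper()
    if code in STANDARD_AA:
        return code
    if code in THREE_TO_ONE:
        return THREE_TO_ONE[code]
    raise KeyError(f"not a standard amino acid: {code!r}")
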