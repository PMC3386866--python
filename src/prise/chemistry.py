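"""Chemical reference tables.

Heavy-atom compositions of the 20 standard amino acids, the 36-name
atom-nomenclature vocabulary derived from them, Van der Waals radii, and
the three-letter/one-letter residue code mapping.
"""

from __future__ import annotations

import logging

logger = logging.getLogger("prise")

#: Heavy (non-hydrogen) PDB atom names of the 20 standard amino acids.
#: The terminal OXT is handled separately: it contributes to residue ASA
#: but is not part of the nomenclature vocabulary.
RESIDUE_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}

STANDARD_RESIDUES = frozenset(RESIDUE_ATOMS)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: The 36 distinct heavy-atom nomenclatures occurring in the 20 standard
#: amino acids, in fixed order.  This order defines the histogram bins.
ATOM_VOCABULARY: tuple[str, ...] = (
    "N", "CA", "C", "O", "CB",
    "CG", "CG1", "CG2", "CD", "CD1", "CD2",
    "CE", "CE1", "CE2", "CE3", "CZ", "CZ2", "CZ3", "CH2",
    "ND1", "ND2", "NE", "NE1", "NE2", "NH1", "NH2", "NZ",
    "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
    "SD", "SG",
)

VOCABULARY_INDEX: dict[str, int] = {n: i for i, n in enumerate(ATOM_VOCABULARY)}

# Van der Waals radius table (Å), NACCESS/Chothia-style values.
# The backbone carbonyl carbon is trigonal (1.76 Å); all other carbons
# are treated as tetrahedral (1.87 Å).
VDW_RADII: dict[str, float] = {
    "C_carbonyl": 1.76,   # backbone C
    "C_other":    1.87,   # CA and all side-chain carbons
    "N":          1.65,
    "O":          1.40,
    "S":          1.85,
}

DEFAULT_VDW_RADIUS = 1.80

_seen_unknown_names: set[str] = set()


def element_of(atom_name: str) -> str:
    """Infer the chemical element from a heavy-atom PDB name.

    For standard amino-acid heavy atoms the first character of the
    stripped name is the element symbol (C, N, O or S).
    """
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    return name[0].upper()


def vdw_radius(atom_name: str, element: str | None = None,
               radii: dict[str, float] | None = None,
               default: float = DEFAULT_VDW_RADIUS) -> float:
    """Look up the Van der Waals radius for a heavy atom.

    Unknown names fall back to ``default`` (logged once per name).
    """
    table = VDW_RADII if radii is None else radii
    name = atom_name.strip().upper()
    elem = (element or "").strip().upper() or (name[:1] if name else "")
    if elem == "C":
        return table["C_carbonyl"] if name == "C" else table["C_other"]
    if elem in ("N", "O", "S"):
        return table[elem]
    if name not in _seen_unknown_names:
        _seen_unknown_names.add(name)
        logger.warning("unknown atom name %r: using default radius %.2f",
                       atom_name, default)
    return default
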