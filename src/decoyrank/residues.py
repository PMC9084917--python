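"""Heavy-atom topology of the 20 standard amino acids.

Atom names follow PDB v3 conventions. Only non-hydrogen atoms are listed,
since all structure handling in this package is heavy-atom only. The
canonical within-residue ordering (backbone N, CA, C, O, then side chain
from CB outward, then terminal OXT) is the ordering used for every
deterministic atom selection.
"""

from __future__ import annotations

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

# Side-chain heavy atoms, CB outward, in standard PDB order.
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1", "CG2"),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}

STANDARD_RESIDUES: frozenset[str] = frozenset(SIDECHAIN_ATOMS)

ONE_TO_THREE: dict[str, str] = {
    "G": "GLY", "A": "ALA", "S": "SER", "C": "CYS", "T": "THR",
    "V": "VAL", "L": "LEU", "I": "ILE", "M": "MET", "P": "PRO",
    "F": "PHE", "Y": "TYR", "W": "TRP", "D": "ASP", "E": "GLU",
    "N": "ASN", "Q": "GLN", "H": "HIS", "K": "LYS", "R": "ARG",
}
THREE_TO_ONE: dict[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

# Heavy-atom van der Waals radii (Angstrom). A single published table
# (Bondi-style values commonly used for protein SASA); configurable at the
# SASA call site since radii conventions differ slightly between programs.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def heavy_atoms(res_name: str) -> tuple[str, ...]:
    """All heavy-atom names of a standard residue, canonical order, no OXT."""
    return BACKBONE_ATOMS + SIDECHAIN_ATOMS[res_name]


def canonical_order_key(res_name: str, atom_name: str) -> tuple[int, str]:
    """Sort key placing atoms in canonical within-residue order.

    Unknown atom names sort after all known ones, alphabetically, so the
    ordering is total and deterministic for any input.
    """
    if atom_name == "OXT":
        return (10_000, atom_name)
    try:
        names = heavy_atoms(res_name)
    except KeyError:
        return (20_000, atom_name)
    try:
        return (names.index(atom_name), atom_name)
    except ValueError:
        return (20_000, atom_name)


def element_of(atom_name: str) -> str:
    """Element symbol from a heavy-atom PDB name (first character)."""
    return atom_name[0]
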