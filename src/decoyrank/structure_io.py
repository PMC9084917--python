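"""Reading, validating and writing peptide/MHC complex structures.

A complex is a 9-residue peptide (numbered 1-9) bound in the groove of a
class I MHC heavy chain whose residues 1-180 form the binding platform.
Structures are held heavy-atom only: hydrogens are dropped on read, the
first alternate-location conformer is kept, and waters/heteroatoms are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .residues import (
    BACKBONE_ATOMS,
    STANDARD_RESIDUES,
    canonical_order_key,
)

__all__ = [
    "ComplexStructure",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
]

ATOM_CLASSES = ("CA", "heavy", "backbone", "sidechain")


class StructureError(ValueError):
    """Raised for malformed or invariant-violating structures."""


@dataclass
class ComplexStructure:
    """Parsed heavy atoms of one peptide/MHC model.

    Arrays are parallel, one entry per atom. ``peptide_chain`` and
    ``heavy_chain`` name the 9-mer peptide and MHC heavy chain.
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    peptide_chain: str
    heavy_chain: str
    id: str = ""
    _index: dict | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.atom_name)

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            self.chain_id.copy(), self.res_id.copy(), self.res_name.copy(),
            self.atom_name.copy(), self.element.copy(), self.coord.copy(),
            self.peptide_chain, self.heavy_chain, self.id,
        )

    # -- convenience views -------------------------------------------------
    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def peptide_sequence(self) -> str:
        from .residues import THREE_TO_ONE
        m = self.chain_mask(self.peptide_chain)
        seq = []
        for pos in range(1, 10):
            names = self.res_name[m & (self.res_id == pos)]
            seq.append(THREE_TO_ONE.get(names[0], "X") if len(names) else "-")
        return "".join(seq)

    def validate(self) -> None:
        """Check the peptide/MHC invariants; raise StructureError if broken."""
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        bad = set(np.unique(self.res_name)) - STANDARD_RESIDUES
        if bad:
            raise StructureError(f"non-standard residues: {sorted(bad)}")
        pep = self.chain_mask(self.peptide_chain)
        if not pep.any():
            raise StructureError(f"chain not found: {self.peptide_chain!r}")
        pep_res = np.unique(self.res_id[pep])
        if len(pep_res) != 9 or not np.array_equal(pep_res, np.arange(1, 10)):
            raise StructureError(
                f"not a nonamer: peptide chain {self.peptide_chain!r} has "
                f"residues {pep_res.tolist()}, expected 1-9"
            )
        hc = self.chain_mask(self.heavy_chain)
        if not hc.any():
            raise StructureError(f"chain not found: {self.heavy_chain!r}")
        groove = np.unique(self.res_id[hc & (self.atom_name == "CA")])
        missing = set(range(1, 181)) - set(groove.tolist())
        if missing:
            raise StructureError(
                f"heavy chain missing CA for groove residues "
                f"{sorted(missing)[:8]}{'...' if len(missing) > 8 else ''}"
            )
        # every residue (any chain) must carry a CA atom
        for ch in np.unique(self.chain_id):
            cm = self.chain_mask(ch)
            with_ca = set(self.res_id[cm & (self.atom_name == "CA")].tolist())
            all_res = set(self.res_id[cm].tolist())
            if all_res - with_ca:
                raise StructureError(
                    f"chain {ch!r}: residues without CA: "
                    f"{sorted(all_res - with_ca)[:8]}"
                )


def _from_atom_array(arr, peptide_chain, heavy_chain, label) -> ComplexStructure:
    return ComplexStructure(
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name, dtype="U3"),
        atom_name=np.asarray(arr.atom_name, dtype="U4"),
        element=np.asarray(arr.element, dtype="U2"),
        coord=np.asarray(arr.coord, dtype=float),
        peptide_chain=peptide_chain,
        heavy_chain=heavy_chain,
        id=label,
    )


def read_pdb(
    path,
    peptide_chain: str = "P",
    heavy_chain: str = "A",
    *,
    label: str | None = None,
    renumber_peptide: bool = False,
    validate: bool = True,
) -> ComplexStructure:
    """Read a PDB file into a validated :class:`ComplexStructure`.

    Hydrogens are dropped, the first alt-loc conformer is kept, and waters
    and heteroatoms are excluded. Author residue numbering is preserved;
    with ``renumber_peptide`` a peptide numbered consecutively but not
    starting at 1 is shifted to 1-9.
    """
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises on malformed records
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    keep = (
        ~arr.hetero
        & ~np.isin(arr.element, ("H", "D"))
        & (arr.res_name != "HOH")
    )
    arr = arr[keep]
    if arr.array_length() == 0:
        raise StructureError(f"no protein atoms in {path}")
    cs = _from_atom_array(
        arr, peptide_chain, heavy_chain,
        label if label is not None else str(path),
    )
    if renumber_peptide:
        pep = cs.chain_mask(peptide_chain)
        res = np.unique(cs.res_id[pep])
        if len(res) == 9 and np.array_equal(res, np.arange(res[0], res[0] + 9)):
            cs.res_id[pep] = cs.res_id[pep] - res[0] + 1
    if validate:
        cs.validate()
    return cs


def write_pdb(structure: ComplexStructure, path) -> None:
    """Write standard fixed-width ATOM records (coordinates to 3 decimals)."""
    n = len(structure)
    if n == 0:
        raise StructureError("nothing to write")
    arr = struc.AtomArray(n)
    arr.coord = structure.coord.astype(np.float32)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_id
    arr.res_name = structure.res_name
    arr.atom_name = structure.atom_name
    arr.element = structure.element
    arr.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def select_atoms(
    structure: ComplexStructure,
    chain: str,
    residue_range: tuple[int, int],
    atom_class: str,
) -> np.ndarray:
    """Indices of the requested atoms, in deterministic canonical order.

    ``atom_class``: CA (alpha carbons), heavy (all non-hydrogen), backbone
    (N, CA, C, O and OXT when present), sidechain (heavy minus backbone).
    Output is ordered by (residue number, canonical atom-name order) and is
    invariant to the order of records in the input.
    """
    if atom_class not in ATOM_CLASSES:
        raise ValueError(f"unknown atom class {atom_class!r}")
    lo, hi = residue_range
    mask = (
        structure.chain_mask(chain)
        & (structure.res_id >= lo)
        & (structure.res_id <= hi)
    )
    if not mask.any():
        raise StructureError(
            f"no atoms matched: chain {chain!r} residues {lo}-{hi}"
        )
    names = structure.atom_name
    if atom_class == "CA":
        mask &= names == "CA"
    elif atom_class == "backbone":
        mask &= np.isin(names, BACKBONE_ATOMS + ("OXT",))
    elif atom_class == "sidechain":
        # legitimately empty for glycine-only selections
        mask &= ~np.isin(names, BACKBONE_ATOMS + ("OXT",))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx
    order = sorted(
        range(idx.size),
        key=lambda i: (
            structure.res_id[idx[i]],
            canonical_order_key(
                structure.res_name[idx[i]], structure.atom_name[idx[i]]
            ),
        ),
    )
    return idx[np.asarray(order)]
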