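"""Superposition, peptide RMSD and solvent-accessible surface area.

The RMSD convention throughout: the reference (crystal) structure is rigidly
superposed onto the decoy using ONLY the Calpha atoms of MHC heavy-chain
residues 1-180 (the binding groove); peptide deviations are then measured in
that frame with no further fitting on peptide atoms. This isolates how well
the peptide itself is modeled, independent of trivial whole-complex motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .residues import VDW_RADII, canonical_order_key
from .structure_io import ComplexStructure, StructureError, select_atoms

__all__ = [
    "Superposition",
    "RmsdReport",
    "SasaResult",
    "kabsch_fit",
    "groove_superpose",
    "peptide_rmsd",
    "stratified_rmsd",
    "shrake_rupley",
]

GROOVE_RANGE = (1, 180)
RMSD_CLASSES = ("CA", "heavy", "backbone", "sidechain")


@dataclass
class Superposition:
    """Least-squares rigid transform x -> R x + t (proper rotation)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    fit_rmsd: float  # Angstrom over the fitted atom set

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdReport:
    """Global and per-position peptide RMSDs for each atom class."""

    ca_rmsd: float
    ha_rmsd: float
    backbone_rmsd: float
    sidechain_rmsd: float
    per_position: dict  # class -> (9,) array, NaN where no atoms (Gly sidechain)
    n_atoms: dict  # class -> paired-atom count
    per_position_n: dict  # class -> (9,) int array


@dataclass
class SasaResult:
    """Shrake-Rupley solvent accessibility of a complex.

    ``per_residue_sasa``/``per_residue_hsasa`` cover the 9 peptide positions;
    hydrophobic SASA counts atoms whose element passes the hydrophobic
    predicate (carbon and sulfur by default).
    """

    per_atom_area: np.ndarray  # Angstrom^2, one entry per atom considered
    atom_index: np.ndarray  # indices into the source structure
    per_residue_sasa: np.ndarray  # (9,)
    per_residue_hsasa: np.ndarray  # (9,)
    probe_radius: float
    n_sphere_points: int


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Positional pairing; reflections are excluded (proper rotation only).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"point sets must both be (n, 3): {mobile.shape} vs {reference.shape}"
        )
    if len(mobile) < 3:
        raise ValueError("need at least 3 points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mobile @ rot.T + trans
    fit_rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, fit_rmsd=fit_rmsd)


def _groove_ca_map(structure: ComplexStructure) -> dict[int, np.ndarray]:
    idx = select_atoms(structure, structure.heavy_chain, GROOVE_RANGE, "CA")
    return {int(structure.res_id[i]): structure.coord[i] for i in idx}


def groove_superpose(
    crystal: ComplexStructure, decoy: ComplexStructure
) -> tuple[ComplexStructure, Superposition]:
    """Move the crystal into the decoy frame via groove Calpha atoms only.

    Uses the common subset of heavy-chain residues 1-180 present in both
    (warning if either is incomplete). Peptide atoms are carried along by
    the rigid transform but take no part in the fit.
    """
    ca_c = _groove_ca_map(crystal)
    ca_d = _groove_ca_map(decoy)
    common = sorted(set(ca_c) & set(ca_d))
    n_expect = GROOVE_RANGE[1] - GROOVE_RANGE[0] + 1
    if len(common) < 3:
        raise StructureError(
            f"fewer than 3 common groove residues ({len(common)})"
        )
    if len(common) < n_expect:
        warnings.warn(
            f"groove superposition uses {len(common)}/{n_expect} common "
            f"Calpha pairs", stacklevel=2,
        )
    mobile = np.array([ca_c[r] for r in common])
    reference = np.array([ca_d[r] for r in common])
    sup = kabsch_fit(mobile, reference)
    moved = crystal.copy()
    moved.coord = sup.apply(moved.coord)
    return moved, sup


def _peptide_atom_map(
    structure: ComplexStructure, atom_class: str
) -> dict[tuple[int, str], np.ndarray]:
    try:
        idx = select_atoms(structure, structure.peptide_chain, (1, 9), atom_class)
    except StructureError:
        return {}
    return {
        (int(structure.res_id[i]), str(structure.atom_name[i])): structure.coord[i]
        for i in idx
    }


def _paired_deviations(
    crystal: ComplexStructure,
    decoy: ComplexStructure,
    atom_class: str,
    max_missing_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Squared deviations and residue ids of name-paired peptide atoms.

    Atoms are paired by (residue number, atom name). A terminal OXT present
    in only one structure is silently dropped; other unpaired atoms are
    skipped with a warning, and more than ``max_missing_fraction`` unpaired
    is an error.
    """
    a = _peptide_atom_map(crystal, atom_class)
    b = _peptide_atom_map(decoy, atom_class)
    common = set(a) & set(b)
    unpaired = (set(a) ^ set(b)) - {k for k in (set(a) ^ set(b)) if k[1] == "OXT"}
    n_total = len(common) + len(unpaired)
    if n_total == 0:
        return np.empty(0), np.empty(0, dtype=int)
    if unpaired:
        frac = len(unpaired) / n_total
        if frac > max_missing_fraction:
            raise StructureError(
                f"{len(unpaired)}/{n_total} peptide atoms unpaired in class "
                f"{atom_class} (> {max_missing_fraction:.0%})"
            )
        warnings.warn(
            f"skipping {len(unpaired)} unpaired peptide atoms "
            f"(class {atom_class})", stacklevel=3,
        )
    keys = sorted(
        common,
        key=lambda k: (k[0], canonical_order_key("XXX", k[1])[1]),
    )
    sq = np.array([np.sum((a[k] - b[k]) ** 2) for k in keys])
    res = np.array([k[0] for k in keys], dtype=int)
    return sq, res


def peptide_rmsd(
    crystal: ComplexStructure,
    decoy: ComplexStructure,
    atom_class: str = "heavy",
    *,
    superpose: bool = True,
    max_missing_fraction: float = 0.1,
) -> float:
    """Peptide RMSD of the given atom class in the groove-superposed frame.

    With ``superpose`` (default) the crystal is first moved into the decoy
    frame via :func:`groove_superpose`; set it False if that was already
    done. No fitting is ever performed on peptide atoms.
    """
    if superpose:
        crystal, _ = groove_superpose(crystal, decoy)
    sq, _ = _paired_deviations(crystal, decoy, atom_class, max_missing_fraction)
    if sq.size == 0:
        raise StructureError(f"no paired peptide atoms for class {atom_class}")
    return float(np.sqrt(sq.mean()))


def stratified_rmsd(
    crystal: ComplexStructure,
    decoy: ComplexStructure,
    *,
    superpose: bool = True,
    max_missing_fraction: float = 0.1,
) -> RmsdReport:
    """Global and per-position RMSDs for all atom classes at once."""
    if superpose:
        crystal, _ = groove_superpose(crystal, decoy)
    glob: dict[str, float] = {}
    per_pos: dict[str, np.ndarray] = {}
    n_atoms: dict[str, int] = {}
    per_pos_n: dict[str, np.ndarray] = {}
    for cls in RMSD_CLASSES:
        sq, res = _paired_deviations(
            crystal, decoy, cls, max_missing_fraction
        )
        pos_val = np.full(9, np.nan)
        pos_n = np.zeros(9, dtype=int)
        for p in range(1, 10):
            m = res == p
            pos_n[p - 1] = int(m.sum())
            if m.any():
                pos_val[p - 1] = float(np.sqrt(sq[m].mean()))
        glob[cls] = float(np.sqrt(sq.mean())) if sq.size else np.nan
        per_pos[cls] = pos_val
        n_atoms[cls] = int(sq.size)
        per_pos_n[cls] = pos_n
    return RmsdReport(
        ca_rmsd=glob["CA"],
        ha_rmsd=glob["heavy"],
        backbone_rmsd=glob["backbone"],
        sidechain_rmsd=glob["sidechain"],
        per_position=per_pos,
        n_atoms=n_atoms,
        per_position_n=per_pos_n,
    )


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    structure: ComplexStructure,
    probe: float = 1.4,
    n_points: int = 960,
    *,
    radii: dict[str, float] | None = None,
    hydrophobic_elements: tuple[str, ...] = ("C", "S"),
    chains: tuple[str, ...] | None = None,
) -> SasaResult:
    """Shrake-Rupley SASA with a deterministic golden-spiral point set.

    Computed in the bound-state context by default (all chains present);
    ``chains`` restricts the atom universe, e.g. the free peptide alone.
    Per-residue totals are reported for the 9 peptide positions; hydrophobic
    SASA sums atoms whose element is in ``hydrophobic_elements``.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for usable quadrature")
    radii = dict(VDW_RADII if radii is None else radii)
    if chains is None:
        idx = np.arange(len(structure))
    else:
        idx = np.flatnonzero(np.isin(structure.chain_id, chains))
        if idx.size == 0:
            raise StructureError(f"no atoms in chains {chains}")
    elements = structure.element[idx]
    unknown = set(elements.tolist()) - set(radii)
    if unknown:
        raise StructureError(f"no vdW radius for element(s) {sorted(unknown)}")
    coords = structure.coord[idx]
    r_ext = np.array([radii[e] for e in elements]) + probe
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(idx.size)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    for i in range(idx.size):
        # deterministic per-atom rotation of the point set decorrelates
        # quadrature errors across atoms so they cancel in sums
        angle = 2.0 * np.pi * ((i * golden) % 1.0)
        axis = np.array([np.cos(2.4 * i), np.sin(2.4 * i), np.cos(1.7 * i + 1.0)])
        axis /= np.linalg.norm(axis)
        rot = _axis_angle_matrix(axis, angle)
        pts = coords[i] + r_ext[i] * (sphere @ rot.T)
        neighbors = tree.query_ball_point(coords[i], r_ext[i] + r_ext.max())
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > r_ext[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * r_ext[i] ** 2
    pep_sasa = np.zeros(9)
    pep_hsasa = np.zeros(9)
    pep_mask = structure.chain_id[idx] == structure.peptide_chain
    res_ids = structure.res_id[idx]
    hydro = np.isin(elements, hydrophobic_elements)
    for p in range(1, 10):
        m = pep_mask & (res_ids == p)
        pep_sasa[p - 1] = per_atom[m].sum()
        pep_hsasa[p - 1] = per_atom[m & hydro].sum()
    return SasaResult(
        per_atom_area=per_atom,
        atom_index=idx,
        per_residue_sasa=pep_sasa,
        per_residue_hsasa=pep_hsasa,
        probe_radius=probe,
        n_sphere_points=n_points,
    )
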