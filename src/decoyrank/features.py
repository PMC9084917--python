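"""Decoy feature matrices: per-residue score terms plus SASA/hSASA.

Each decoy contributes one row; columns are (peptide position 1-9) x (term),
named ``p{pos}_{term}``, ordered position-major with terms alphabetical
within a position. The target column is the decoy's true heavy-atom RMSD
when a reference structure is known; total and peptide-only energies ride
along as metadata and are never used as predictor features.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import SasaResult

__all__ = [
    "ResidueScoreTable",
    "FeatureMatrix",
    "TermFilterPolicy",
    "Scaler",
    "read_score_table",
    "assemble_features",
    "filter_terms",
    "fit_scaler",
    "apply_scaler",
    "split_train_test",
    "write_features_csv",
    "read_features_csv",
]

POSITIONS = tuple(range(1, 10))


@dataclass
class ResidueScoreTable:
    """Per-residue score breakdown for one decoy: positions 1-9 x terms."""

    decoy_id: str
    table: pd.DataFrame  # index = position 1-9, columns = term names

    def __post_init__(self) -> None:
        missing = set(POSITIONS) - set(self.table.index)
        if missing:
            raise ValueError(f"missing positions: {sorted(missing)}")
        self.table = self.table.loc[list(POSITIONS)].astype(float)


@dataclass
class Scaler:
    """Per-column centering/scaling parameters (sample sd, n-1)."""

    mean: pd.Series
    sd: pd.Series


@dataclass
class FeatureMatrix:
    """Decoys x feature columns, with optional target/energy metadata."""

    data: pd.DataFrame  # index = decoy ids, columns = p{pos}_{term}
    column_meta: list = field(default_factory=list)  # [(position, term)]
    target: pd.Series | None = None  # true HA RMSD, Angstrom
    energy: pd.Series | None = None  # total score
    peptide_energy: pd.Series | None = None
    scaling: Scaler | None = None
    filter_log: list = field(default_factory=list)

    @property
    def decoy_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_decoys(self) -> int:
        return len(self.data)

    def rows(self, ids) -> "FeatureMatrix":
        """Row subset by decoy id, metadata carried along."""
        sel = list(ids)
        return FeatureMatrix(
            data=self.data.loc[sel],
            column_meta=list(self.column_meta),
            target=None if self.target is None else self.target.loc[sel],
            energy=None if self.energy is None else self.energy.loc[sel],
            peptide_energy=(
                None if self.peptide_energy is None
                else self.peptide_energy.loc[sel]
            ),
            scaling=self.scaling,
            filter_log=list(self.filter_log),
        )


@dataclass
class TermFilterPolicy:
    """A-priori term exclusions plus the zero-variance rule.

    ``exclusion_list`` names terms tied to residue identity (e.g. aromatic
    ring planarity) that must not enter the regression regardless of
    variance; ``min_variance`` defaults to an exact-zero test.
    """

    exclusion_list: tuple[str, ...] = ()
    min_variance: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.exclusion_list)) != len(self.exclusion_list):
            raise ValueError("exclusion list entries must be unique")


def column_name(position: int, term: str) -> str:
    return f"p{position}_{term}"


def read_score_table(
    path_or_buffer,
    dialect: str = "generic_csv",
    *,
    decoy_id: str | None = None,
) -> ResidueScoreTable:
    """Read one decoy's per-residue score table.

    ``generic_csv``: comma-separated with a ``position`` column (1-9) and
    one column per term. ``rosetta_per_residue``: whitespace-separated lines
    starting with ``SCORE:``; the header names the terms and ends with
    ``description``, each data row's description ends in ``_<position>``.
    """
    if dialect == "generic_csv":
        df = pd.read_csv(path_or_buffer)
        if "position" not in df.columns:
            raise ValueError("generic_csv requires a 'position' column")
        df = df.set_index("position")
        name = decoy_id or getattr(path_or_buffer, "name", str(path_or_buffer))
        return ResidueScoreTable(decoy_id=str(name), table=df)
    if dialect == "rosetta_per_residue":
        if hasattr(path_or_buffer, "read"):
            text = path_or_buffer.read()
        else:
            with open(path_or_buffer) as fh:
                text = fh.read()
        header = None
        rows = {}
        desc_stem = None
        for line in text.splitlines():
            if not line.strip().startswith("SCORE:"):
                continue
            fields = line.split()[1:]
            if header is None:
                if fields[-1] != "description":
                    raise ValueError(
                        "rosetta_per_residue header must end in 'description'"
                    )
                header = fields[:-1]
                continue
            desc = fields[-1]
            stem, _, pos_txt = desc.rpartition("_")
            try:
                pos = int(pos_txt)
            except ValueError as exc:
                raise ValueError(f"bad description field {desc!r}") from exc
            desc_stem = desc_stem or stem
            rows[pos] = [float(v) for v in fields[:-1]]
        if header is None:
            raise ValueError("no SCORE: header found")
        df = pd.DataFrame.from_dict(rows, orient="index", columns=header)
        df.index.name = "position"
        return ResidueScoreTable(
            decoy_id=decoy_id or desc_stem or "decoy", table=df.sort_index()
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def assemble_features(
    tables: list[ResidueScoreTable],
    sasa: dict[str, SasaResult] | None = None,
    *,
    target: pd.Series | None = None,
    energy: pd.Series | None = None,
    peptide_energy: pd.Series | None = None,
) -> FeatureMatrix:
    """Stack per-decoy score tables (plus SASA/hSASA) into a FeatureMatrix.

    All decoys must share one term universe. Column order is deterministic:
    position-major, term names alphabetical within each position.
    """
    if not tables:
        raise ValueError("no score tables given")
    terms = set(tables[0].table.columns)
    for t in tables[1:]:
        if set(t.table.columns) != terms:
            raise ValueError(
                f"inconsistent term universe for decoy {t.decoy_id!r}"
            )
    if sasa is not None:
        if {"sasa", "hsasa"} & terms:
            raise ValueError("score terms clash with sasa/hsasa columns")
        terms |= {"sasa", "hsasa"}
    term_order = sorted(terms)
    meta = [(p, term) for p in POSITIONS for term in term_order]
    columns = [column_name(p, term) for p, term in meta]
    ids = [t.decoy_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate decoy ids")
    values = np.empty((len(tables), len(columns)))
    for i, t in enumerate(tables):
        cells = {}
        for p in POSITIONS:
            for term in t.table.columns:
                cells[(p, term)] = t.table.at[p, term]
        if sasa is not None:
            s = sasa[t.decoy_id]
            for p in POSITIONS:
                cells[(p, "sasa")] = s.per_residue_sasa[p - 1]
                cells[(p, "hsasa")] = s.per_residue_hsasa[p - 1]
        values[i] = [cells[m] for m in meta]
    df = pd.DataFrame(values, index=ids, columns=columns)
    df = df.sort_index(kind="stable")

    def _align(s: pd.Series | None) -> pd.Series | None:
        return None if s is None else s.loc[df.index].astype(float)

    return FeatureMatrix(
        data=df,
        column_meta=[meta[columns.index(c)] for c in df.columns],
        target=_align(target),
        energy=_align(energy),
        peptide_energy=_align(peptide_energy),
    )


def filter_terms(
    matrix: FeatureMatrix, policy: TermFilterPolicy = TermFilterPolicy()
) -> FeatureMatrix:
    """Drop excluded-by-name terms and zero-variance columns.

    Idempotent; logs every removal in ``filter_log``. All-columns-removed is
    an error (empty feature matrix is useless downstream).
    """
    if matrix.scaling is not None:
        raise ValueError("filter_terms must run on an unscaled matrix")
    log = list(matrix.filter_log)
    keep = []
    meta_keep = []
    for (pos, term), col in zip(matrix.column_meta, matrix.data.columns):
        if term in policy.exclusion_list:
            log.append(f"excluded by name: {col}")
            continue
        var = float(matrix.data[col].var(ddof=1)) if matrix.n_decoys > 1 else 0.0
        if var <= policy.min_variance:
            log.append(f"removed (variance {var:g}): {col}")
            continue
        keep.append(col)
        meta_keep.append((pos, term))
    if not keep:
        raise ValueError("empty feature matrix after filtering")
    return FeatureMatrix(
        data=matrix.data[keep],
        column_meta=meta_keep,
        target=matrix.target,
        energy=matrix.energy,
        peptide_energy=matrix.peptide_energy,
        filter_log=log,
    )


def fit_scaler(matrix: FeatureMatrix) -> Scaler:
    """Per-column mean and sample standard deviation (n-1 denominator)."""
    mean = matrix.data.mean()
    sd = matrix.data.std(ddof=1)
    if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(sd)):
        raise ValueError("non-finite scaling parameters")
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero-sd columns (run filter_terms first): {bad[:5]}")
    return Scaler(mean=mean, sd=sd)


def apply_scaler(matrix: FeatureMatrix, scaler: Scaler) -> FeatureMatrix:
    """Center/scale columns with a previously fitted scaler (no refitting)."""
    missing = set(matrix.data.columns) - set(scaler.mean.index)
    if missing:
        raise ValueError(f"scaler lacks columns: {sorted(missing)[:5]}")
    scaled = (matrix.data - scaler.mean[matrix.data.columns]) / (
        scaler.sd[matrix.data.columns]
    )
    return replace(matrix, data=scaled, scaling=scaler)


def split_train_test(
    matrix: FeatureMatrix,
    fraction: float = 0.8,
    seed: int = 0,
    stratify_bins: int = 1,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded random train/test split of decoy rows.

    With ``stratify_bins > 1`` rows are binned by target quantiles and split
    within bins (largest-remainder allocation to hit the exact train count),
    so the train and test RMSD distributions are comparable.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if matrix.target is None:
        raise ValueError("split requires a target column")
    rng = np.random.default_rng(seed)
    n = matrix.n_decoys
    n_train = int(round(fraction * n))
    y = matrix.target.to_numpy()
    if stratify_bins <= 1:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    else:
        order = np.argsort(y, kind="stable")
        bins = np.array_split(order, stratify_bins)
        quota = [fraction * len(b) for b in bins]
        base = [int(np.floor(q)) for q in quota]
        short = n_train - sum(base)
        remainders = np.array(quota) - np.array(base)
        for b in np.argsort(-remainders, kind="stable")[:short]:
            base[b] += 1
        chosen = []
        for b, k in zip(bins, base):
            b = rng.permutation(b)
            chosen.extend(b[:k].tolist())
        train_idx = np.sort(np.array(chosen, dtype=int))
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    ids = np.asarray(matrix.decoy_ids)
    return matrix.rows(ids[mask]), matrix.rows(ids[~mask])


def write_features_csv(matrix: FeatureMatrix, path) -> None:
    """Feature CSV: decoy_id, target/energy metadata, then p{pos}_{term}."""
    df = matrix.data.copy()
    front = {}
    if matrix.target is not None:
        front["target_ha_rmsd"] = matrix.target
    if matrix.energy is not None:
        front["total_energy"] = matrix.energy
    if matrix.peptide_energy is not None:
        front["peptide_energy"] = matrix.peptide_energy
    out = pd.concat([pd.DataFrame(front, index=df.index), df], axis=1)
    out.index.name = "decoy_id"
    out.to_csv(path)


def read_features_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="decoy_id", comment="#")
    df.index = df.index.astype(str)
    meta_cols = [
        c for c in ("target_ha_rmsd", "total_energy", "peptide_energy")
        if c in df.columns
    ]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    meta = []
    for c in feat_cols:
        if not c.startswith("p"):
            raise ValueError(f"unrecognized feature column {c!r}")
        pos_txt, _, term = c[1:].partition("_")
        meta.append((int(pos_txt), term))
    return FeatureMatrix(
        data=df[feat_cols],
        column_meta=meta,
        target=df["target_ha_rmsd"] if "target_ha_rmsd" in meta_cols else None,
        energy=df["total_energy"] if "total_energy" in meta_cols else None,
        peptide_energy=(
            df["peptide_energy"] if "peptide_energy" in meta_cols else None
        ),
    )
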