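"""Decoy ranking, optimal-decoy selection and the evaluation battery.

Given per-target decoy ensembles (features, energies and — when the
reference structure is known — true RMSDs), this module ranks decoys by any
criterion, selects the optimal decoy per target, compares selection methods
across targets with paired significance tests, and stratifies residual
error by peptide position and amino-acid identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .regression import RegressionModel, predict

__all__ = [
    "DecoyEnsemble",
    "RankingResult",
    "SelectionComparison",
    "StratifiedErrorTable",
    "rank_decoys",
    "spearman",
    "select_optimal",
    "compare_methods",
    "wilcoxon_signed_rank",
    "paired_t",
    "stratify_errors",
    "DegenerateEnsembleWarning",
]

BUILTIN_CRITERIA = ("true_ha_rmsd", "total_energy", "peptide_energy")


class DegenerateEnsembleWarning(UserWarning):
    """All decoys indistinguishable under the criterion (no good vs bad)."""


@dataclass
class DecoyEnsemble:
    """All decoys of one modeling target, with features and ground truth."""

    target_id: str
    features: FeatureMatrix
    true_ca_rmsd: np.ndarray | None = None
    true_ha_rmsd: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.features.n_decoys
        for name in ("true_ca_rmsd", "true_ha_rmsd"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise ValueError(f"{name} length {len(v)} != {n} decoys")
                if (v < 0).any():
                    raise ValueError(f"{name} must be non-negative")
                setattr(self, name, v)

    @property
    def decoy_ids(self) -> list[str]:
        return self.features.decoy_ids

    def criterion_values(self, criterion) -> np.ndarray:
        """Per-decoy values of a selection criterion (lower = better)."""
        if isinstance(criterion, RegressionModel):
            return predict(criterion, self.features)
        if criterion == "true_ha_rmsd":
            if self.true_ha_rmsd is None:
                raise ValueError("true HA RMSD not available")
            return self.true_ha_rmsd
        if criterion == "total_energy":
            if self.features.energy is None:
                raise ValueError("total energy not available")
            return self.features.energy.to_numpy()
        if criterion == "peptide_energy":
            if self.features.peptide_energy is None:
                raise ValueError("peptide energy not available")
            return self.features.peptide_energy.to_numpy()
        raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class RankingResult:
    criterion: str
    decoy_ids: list[str]
    ranks: np.ndarray  # 1..N, ties mid-ranked
    values: np.ndarray
    spearman_vs_true: float  # NaN when undefined


@dataclass
class SelectionComparison:
    """Per-target selections for several methods, plus paired tests."""

    selections: pd.DataFrame  # target x method -> decoy id
    ca_rmsd: pd.DataFrame  # target x method
    ha_rmsd: pd.DataFrame  # target x method
    summary: pd.DataFrame  # method -> mean/median/quartiles of HA RMSD
    tests: pd.DataFrame  # one row per requested (pair, test, alternative)


@dataclass
class StratifiedErrorTable:
    by_position: pd.DataFrame  # index position 1-9, columns atom classes
    by_position_aa: pd.DataFrame  # long: position, amino_acid, mean_ha, count
    min_count: int


def spearman(a, b) -> float:
    """Tie-aware Spearman rho (Pearson correlation of mid-ranks).

    Returns NaN with a warning when either input is constant (rho is then
    undefined — the degenerate tightly-clustered ensemble case).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            "constant input: Spearman correlation undefined (all decoys "
            "equivalent under this criterion)",
            DegenerateEnsembleWarning, stacklevel=2,
        )
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def rank_decoys(ensemble: DecoyEnsemble, criterion) -> RankingResult:
    """Rank decoys 1..N (1 = best) by ascending criterion value.

    Ties receive average (mid) ranks. When true HA RMSD is available and
    the criterion is not itself the truth, the Spearman correlation of the
    criterion against truth is attached.
    """
    values = ensemble.criterion_values(criterion)
    ranks = stats.rankdata(values, method="average")
    rho = float("nan")
    if ensemble.true_ha_rmsd is not None:
        if np.ptp(values) == 0:
            warnings.warn(
                f"target {ensemble.target_id}: all decoys tied under "
                f"criterion; rank correlation undefined",
                DegenerateEnsembleWarning, stacklevel=2,
            )
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateEnsembleWarning)
                rho = spearman(values, ensemble.true_ha_rmsd)
    name = (
        f"predicted_rmsd:{criterion.kind}"
        if isinstance(criterion, RegressionModel) else str(criterion)
    )
    return RankingResult(
        criterion=name, decoy_ids=ensemble.decoy_ids,
        ranks=ranks, values=np.asarray(values, dtype=float),
        spearman_vs_true=rho,
    )


def _method_criterion(method):
    if isinstance(method, RegressionModel):
        return method
    if method == "best_true":
        return "true_ha_rmsd"
    if method == "lowest_total_energy":
        return "total_energy"
    if method == "lowest_peptide_energy":
        return "peptide_energy"
    raise ValueError(f"unknown selection method {method!r}")


def select_optimal(ensemble: DecoyEnsemble, method) -> tuple[str, float, float]:
    """Argmin decoy under the method's criterion.

    ``method`` is ``best_true``, ``lowest_total_energy``,
    ``lowest_peptide_energy`` or a fitted :class:`RegressionModel`.
    Ties break to the lexically first decoy id. Returns
    (decoy id, its true Calpha RMSD, its true HA RMSD) with NaN where truth
    is unknown.
    """
    if ensemble.features.n_decoys == 0:
        raise ValueError("empty ensemble")
    values = ensemble.criterion_values(_method_criterion(method))
    ids = np.asarray(ensemble.decoy_ids)
    best = values.min()
    tied = ids[values == best]
    chosen = sorted(tied)[0]
    i = int(np.flatnonzero(ids == chosen)[0])
    ca = float(ensemble.true_ca_rmsd[i]) if ensemble.true_ca_rmsd is not None else float("nan")
    ha = float(ensemble.true_ha_rmsd[i]) if ensemble.true_ha_rmsd is not None else float("nan")
    return chosen, ca, ha


def wilcoxon_signed_rank(
    differences, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test on paired differences.

    Zero differences are dropped. The exact null distribution is used for
    n <= 25 without ties in |d|; otherwise the tie-corrected normal
    approximation. ``alternative='greater'`` tests for differences > 0.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 5:
        raise ValueError("need >= 5 nonzero differences")
    alt = alternative.replace("_", "-")
    if alt not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    abs_d = np.abs(d)
    exact = d.size <= 25 and len(np.unique(abs_d)) == abs_d.size
    res = stats.wilcoxon(
        d, alternative=alt, method="exact" if exact else "approx",
        correction=False,
    )
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y=None, alternative: str = "two_sided") -> tuple[float, float]:
    """Paired t test. With ``y=None``, ``x`` is taken as the differences."""
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(d) == 0:
        raise ValueError("zero-variance differences: t undefined")
    alt = alternative.replace("_", "-")
    res = stats.ttest_rel(d, np.zeros_like(d), alternative=alt)
    return float(res.statistic), float(res.pvalue)


def _method_name(method) -> str:
    if isinstance(method, RegressionModel):
        return f"model:{method.kind}"
    return str(method)


def compare_methods(
    ensembles: list[DecoyEnsemble],
    methods: dict | list,
    tests: list[tuple] | None = None,
) -> SelectionComparison:
    """Select one decoy per target per method and compare methods.

    ``methods`` maps display name -> method spec (or is a list of specs,
    named automatically). ``tests`` is a list of
    ((method_a, method_b), test, alternative) with test in
    {"wilcoxon", "ttest"}; the paired statistic is computed on per-target
    (a - b) HA RMSD differences, so ``alternative="less"`` asks whether
    method a selects lower-RMSD decoys than method b.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least 2 targets")
    if not isinstance(methods, dict):
        methods = {_method_name(m): m for m in methods}
    targets = [e.target_id for e in ensembles]
    sel = pd.DataFrame(index=targets, columns=list(methods), dtype=object)
    ca = pd.DataFrame(index=targets, columns=list(methods), dtype=float)
    ha = pd.DataFrame(index=targets, columns=list(methods), dtype=float)
    for e in ensembles:
        for name, m in methods.items():
            d, c, h = select_optimal(e, m)
            sel.at[e.target_id, name] = d
            ca.at[e.target_id, name] = c
            ha.at[e.target_id, name] = h
    summary = pd.DataFrame({
        "mean": ha.mean(), "median": ha.median(),
        "q1": ha.quantile(0.25), "q3": ha.quantile(0.75),
    }).sort_values("mean", kind="stable")
    rows = []
    for (a, b), test, alternative in (tests or []):
        for nm in (a, b):
            if nm not in methods:
                raise ValueError(f"test names unevaluated method {nm!r}")
        diff = (ha[a] - ha[b]).to_numpy()
        if np.all(diff == 0):
            # identical selections: no evidence of any difference
            stat, p = 0.0, 1.0
        elif test == "wilcoxon":
            stat, p = wilcoxon_signed_rank(diff, alternative)
        elif test == "ttest":
            stat, p = paired_t(diff, alternative=alternative)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({
            "method_a": a, "method_b": b, "test": test,
            "alternative": alternative, "statistic": stat, "p": p,
        })
    return SelectionComparison(
        selections=sel, ca_rmsd=ca, ha_rmsd=ha, summary=summary,
        tests=pd.DataFrame(rows),
    )


def stratify_errors(
    reports: dict[str, "RmsdReport"],  # noqa: F821 - geometry.RmsdReport
    sequences: dict[str, str],
    min_count: int = 3,
) -> StratifiedErrorTable:
    """Stratify selected-decoy error by peptide position and amino acid.

    ``reports`` maps target id -> the stratified RMSD report of that
    target's selected decoy; ``sequences`` maps target id -> its 9-mer
    peptide sequence. Per-(position, amino-acid) heavy-atom means are only
    reported for amino acids present at that position in >= ``min_count``
    peptides; rarer cells are absent, not zero.
    """
    by_pos: dict[str, np.ndarray] = {}
    for cls_name, cls_key in (
        ("backbone", "backbone"), ("sidechain", "sidechain"), ("heavy", "heavy"),
    ):
        stack = np.vstack([r.per_position[cls_key] for r in reports.values()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            by_pos[cls_name] = np.nanmean(stack, axis=0)
    pos_df = pd.DataFrame(by_pos, index=pd.Index(range(1, 10), name="position"))
    cells: dict[tuple[int, str], list[float]] = {}
    for tid, rep in reports.items():
        seq = sequences[tid]
        if len(seq) != 9:
            raise ValueError(f"target {tid!r}: sequence length {len(seq)} != 9")
        for p in range(1, 10):
            v = rep.per_position["heavy"][p - 1]
            if np.isfinite(v):
                cells.setdefault((p, seq[p - 1]), []).append(float(v))
    rows = [
        {"position": p, "amino_acid": aa,
         "mean_ha_rmsd": float(np.mean(vals)), "count": len(vals)}
        for (p, aa), vals in sorted(cells.items())
        if len(vals) >= min_count
    ]
    return StratifiedErrorTable(
        by_position=pos_df,
        by_position_aa=pd.DataFrame(
            rows, columns=["position", "amino_acid", "mean_ha_rmsd", "count"]
        ),
        min_count=min_count,
    )
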