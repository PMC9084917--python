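"""Synthetic decoy ensembles with known ground truth.

Two levels of realism, matching what downstream modules need:

* coordinate level — a stylized 9-mer peptide in a 180-residue groove
  scaffold, perturbed into decoy sets whose achieved RMSDs are measured
  through the geometry module (never assumed from the perturbation size);
* feature level — decoy x term matrices with a planted (linear or
  quadratic) dependence of heavy-atom RMSD on features plus noise, and a
  synthetic "total energy" channel with a requested correlation to true
  RMSD, emulating ensembles where energy carries no information about
  model quality.

Every suite records its generating spec and seed; regeneration is
bit-identical. Per-target RNG streams are keyed on (seed, target index) so
adding targets never shifts existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .features import FeatureMatrix, column_name
from .residues import ONE_TO_THREE, element_of, heavy_atoms
from .selection import DecoyEnsemble
from .structure_io import ComplexStructure, write_pdb

__all__ = [
    "EnsembleSpec",
    "SyntheticSuite",
    "make_toy_complex",
    "perturb_decoys",
    "generate_feature_suite",
]

DEFAULT_TERMS = ("atr", "rep", "sol")


@dataclass(frozen=True)
class EnsembleSpec:
    """Study conditions for a feature-level synthetic suite.

    Defaults emulate the regime the evaluation battery targets: per-target
    decoy clouds spanning roughly 0.5-3.5 Angstrom HA RMSD (log-normal
    target centers), within-target sampling breadth set by
    ``per_target_variance`` (Angstrom^2 of HA RMSD), feature-to-RMSD
    residual noise ``noise_sd``, and an energy channel decorrelated from
    true RMSD unless requested otherwise.
    """

    n_targets: int = 40
    n_decoys: int = 200
    rmsd_lognormal_median: float = 1.5  # Angstrom, center of target means
    rmsd_lognormal_sigma: float = 0.35
    rmsd_range: tuple[float, float] = (0.5, 3.5)
    per_target_variance: float = 0.30  # Angstrom^2
    noise_sd: float = 0.15  # Angstrom
    energy_rmsd_correlation: float = 0.0
    planted_model: str = "linear"  # or "quadratic"
    n_terms: int = len(DEFAULT_TERMS)
    n_informative: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys < 2:
            raise ValueError("n_decoys must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(self.energy_rmsd_correlation) > 1:
            raise ValueError("|energy_rmsd_correlation| must be <= 1")
        if self.planted_model not in ("linear", "quadratic"):
            raise ValueError(f"unknown planted model {self.planted_model!r}")


@dataclass
class SyntheticSuite:
    """Generated ensembles plus full provenance (spec + seed)."""

    spec: EnsembleSpec
    ensembles: list[DecoyEnsemble]
    planted_coefficients: pd.Series  # true linear weights on raw columns
    provenance: dict = field(default_factory=dict)

    def pooled(self) -> FeatureMatrix:
        """All targets' decoys stacked into one FeatureMatrix."""
        first = self.ensembles[0].features
        data = pd.concat([e.features.data for e in self.ensembles])
        tgt = pd.concat(
            [e.features.target for e in self.ensembles]
        )
        en = pd.concat([e.features.energy for e in self.ensembles])
        pe = pd.concat(
            [e.features.peptide_energy for e in self.ensembles]
        )
        return FeatureMatrix(
            data=data, column_meta=list(first.column_meta),
            target=tgt, energy=en, peptide_energy=pe,
        )

    def provenance_json(self) -> str:
        doc = dict(self.provenance)
        doc["spec"] = dataclasses.asdict(self.spec)
        return json.dumps(doc, indent=1, default=str)


# ---------------------------------------------------------------------------
# coordinate level
# ---------------------------------------------------------------------------

def make_toy_complex(
    peptide_sequence: str, seed: int = 0,
    *, peptide_chain: str = "P", heavy_chain: str = "A", label: str = "toy",
) -> ComplexStructure:
    """Idealized extended 9-mer in a stylized 180-residue groove scaffold.

    The peptide carries every heavy atom of its residues with roughly
    plausible local geometry (bond lengths are not force-field refined);
    the groove is a Calpha-only cradle of walls and floor flanking the
    peptide, sufficient for groove superposition and bound-state SASA.
    Deterministic for a given (sequence, seed).
    """
    seq = peptide_sequence.upper()
    if len(seq) != 9 or any(c not in ONE_TO_THREE for c in seq):
        raise ValueError(f"invalid 9-mer sequence {peptide_sequence!r}")
    rng = np.random.default_rng([seed, 0x70F])
    chain, res_id, res_name, atom_name, element, coord = [], [], [], [], [], []
    for i, one in enumerate(seq, start=1):
        three = ONE_TO_THREE[one]
        x0 = 3.5 * (i - 1)
        zig = 0.6 if i % 2 else -0.6
        pos = {
            "N": np.array([x0, zig, 0.0]),
            "CA": np.array([x0 + 1.2, zig + 0.6, 0.4]),
            "C": np.array([x0 + 2.4, zig, 0.1]),
            "O": np.array([x0 + 2.7, zig - 0.9, 0.8]),
        }
        names = heavy_atoms(three)
        side = names[4:]
        base = pos["CA"] + np.array([0.0, 0.4, 1.4])
        for k, nm in enumerate(side):
            jitter = rng.normal(scale=0.25, size=3)
            pos[nm] = base + np.array([0.0, 0.15 * k, 1.35 * k]) + jitter
        for nm in names:
            chain.append(peptide_chain)
            res_id.append(i)
            res_name.append(three)
            atom_name.append(nm)
            element.append(element_of(nm))
            coord.append(pos[nm])
    # groove scaffold: two walls and a two-row floor, Calpha only
    xs = np.linspace(-4.0, 33.0, 45)
    layout = [
        (range(1, 46), -4.6, 0.8),
        (range(46, 91), 4.6, 0.8),
        (range(91, 136), -1.5, -3.4),
        (range(136, 181), 1.5, -3.4),
    ]
    for resrange, y, z in layout:
        for j, r in enumerate(resrange):
            chain.append(heavy_chain)
            res_id.append(r)
            res_name.append("GLY")
            atom_name.append("CA")
            element.append("C")
            coord.append(np.array([xs[j], y, z]))
    cs = ComplexStructure(
        chain_id=np.array(chain, dtype="U4"),
        res_id=np.array(res_id, dtype=int),
        res_name=np.array(res_name, dtype="U3"),
        atom_name=np.array(atom_name, dtype="U4"),
        element=np.array(element, dtype="U2"),
        coord=np.array(coord, dtype=float),
        peptide_chain=peptide_chain,
        heavy_chain=heavy_chain,
        id=label,
    )
    cs.validate()
    return cs


def perturb_decoys(
    reference: ComplexStructure,
    n: int,
    spread: float,
    center_bias: np.ndarray | None = None,
    seed: int = 0,
    *, out_dir=None,
) -> tuple[list[ComplexStructure], np.ndarray]:
    """Perturb the peptide into ``n`` decoys; groove atoms are untouched.

    Per-residue Gaussian displacement vectors (sd ``spread`` Angstrom,
    scaled per position by ``center_bias``) are smoothed with a 3-residue
    moving average so neighboring residues move together, keeping local
    geometry roughly sane; a small per-atom jitter differentiates side
    chains. Each decoy additionally draws a log-normal overall scale so the
    ensemble spans a range of RMSDs. Achieved HA RMSDs are measured with
    :func:`decoyrank.geometry.peptide_rmsd` — the single source of truth.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    bias = np.ones(9) if center_bias is None else np.asarray(center_bias, float)
    if bias.shape != (9,) or (bias < 0).any():
        raise ValueError("center_bias must be 9 non-negative weights")
    rng = np.random.default_rng([seed, 0xDEC0])
    pep = reference.chain_mask(reference.peptide_chain)
    decoys: list[ComplexStructure] = []
    achieved = np.empty(n)
    kernel = np.array([0.25, 0.5, 0.25])
    for d in range(n):
        scale = float(np.exp(rng.normal(0.0, 0.4)))
        disp = rng.normal(scale=1.0, size=(9, 3)) * (spread * scale * bias)[:, None]
        smooth = np.empty_like(disp)
        for axis in range(3):
            padded = np.pad(disp[:, axis], 1, mode="edge")
            smooth[:, axis] = np.convolve(padded, kernel, mode="valid")
        decoy = reference.copy()
        decoy.id = f"{reference.id}:{d:04d}"
        for p in range(1, 10):
            m = pep & (reference.res_id == p)
            jitter = rng.normal(scale=0.1 * spread * scale, size=(int(m.sum()), 3))
            decoy.coord[m] = decoy.coord[m] + smooth[p - 1] + jitter
        achieved[d] = geometry.peptide_rmsd(reference, decoy, "heavy")
        if out_dir is not None:
            write_pdb(decoy, f"{out_dir}/decoy_{d:04d}.pdb")
        decoys.append(decoy)
    return decoys, achieved


# ---------------------------------------------------------------------------
# feature level
# ---------------------------------------------------------------------------

def _feature_columns(n_terms: int) -> tuple[list[str], list[tuple[int, str]]]:
    terms = list(DEFAULT_TERMS[:n_terms])
    terms += [f"term{k}" for k in range(len(terms), n_terms)]
    terms = sorted(terms + ["sasa", "hsasa"])
    meta = [(p, t) for p in range(1, 10) for t in terms]
    return [column_name(p, t) for p, t in meta], meta


def _blend_to_correlation(
    y: np.ndarray, rho: float, rng: np.random.Generator,
    tol: float = 0.05, max_tries: int = 50,
) -> np.ndarray:
    """Channel with sample correlation to ``y`` within ``tol`` of ``rho``.

    Closed-form blend of the standardized target with an independent noise
    channel; redrawn (fresh substream) until the sample correlation lands
    inside the tolerance.
    """
    ys = (y - y.mean()) / y.std()
    for _ in range(max_tries):
        g = rng.normal(size=y.size)
        e = rho * ys + np.sqrt(max(0.0, 1.0 - rho * rho)) * g
        if abs(rho) == 1.0 or abs(np.corrcoef(e, y)[0, 1] - rho) <= tol:
            return e
    raise RuntimeError(f"could not achieve energy-RMSD correlation {rho}")


def generate_feature_suite(spec: EnsembleSpec) -> SyntheticSuite:
    """Feature-level suite with a planted feature -> RMSD dependence.

    Per target: decoy feature rows are a correlated Gaussian cloud around a
    target-specific mean chosen so the planted model maps the cloud center
    onto the target's drawn mean RMSD. True HA RMSD = planted(features) +
    N(0, noise_sd), clipped at zero; Calpha RMSD is a proportional shadow.
    Energy channels are blended to the requested correlation with truth.
    """
    columns, meta = _feature_columns(spec.n_terms)
    p = len(columns)
    master = np.random.default_rng([spec.seed, 0])
    mixing = np.eye(p) + 0.3 * master.normal(size=(p, p)) / np.sqrt(p)
    informative = master.choice(p, size=min(spec.n_informative, p), replace=False)
    direction = master.normal(size=informative.size)
    direction /= np.linalg.norm(direction)
    signal_sd = np.sqrt(max(spec.per_target_variance - spec.noise_sd**2, 1e-4))
    beta = np.zeros(p)
    beta[informative] = direction * signal_sd
    lo, hi = spec.rmsd_range
    ensembles: list[DecoyEnsemble] = []
    all_y = []
    for t in range(spec.n_targets):
        rng = np.random.default_rng([spec.seed, 1 + t])
        m_t = float(np.clip(
            spec.rmsd_lognormal_median
            * np.exp(rng.normal(0.0, spec.rmsd_lognormal_sigma)),
            lo, hi,
        ))
        w = rng.normal(size=(spec.n_decoys, p)) @ mixing.T
        mu = beta * (m_t / (beta @ beta))
        x = mu + w
        if spec.planted_model == "linear":
            y = x @ beta
        else:
            i1, i2 = informative[0], informative[1]
            y = m_t + 0.45 * (w[:, i1] ** 2 - 1.0) + 0.35 * w[:, i2]
        y = y + rng.normal(scale=spec.noise_sd, size=spec.n_decoys)
        y = np.maximum(y, 0.01)
        ids = [f"t{t:03d}:d{d:04d}" for d in range(spec.n_decoys)]
        tid = f"t{t:03d}"
        df = pd.DataFrame(x, index=ids, columns=columns)
        ca = np.maximum(0.45 * y + rng.normal(scale=0.05, size=y.size), 0.0)
        fm = FeatureMatrix(
            data=df, column_meta=list(meta),
            target=pd.Series(y, index=ids, name="target_ha_rmsd"),
        )
        ensembles.append(DecoyEnsemble(
            target_id=tid, features=fm, true_ca_rmsd=ca, true_ha_rmsd=y,
        ))
        all_y.append(y)
    y_pool = np.concatenate(all_y)
    erng = np.random.default_rng([spec.seed, 0xE0E])
    e_std = _blend_to_correlation(y_pool, spec.energy_rmsd_correlation, erng)
    pe_std = _blend_to_correlation(y_pool, spec.energy_rmsd_correlation, erng)
    energy = -1250.0 + 4.0 * e_std
    pep_energy = -20.0 + 2.0 * pe_std
    ofs = 0
    for e in ensembles:
        n = e.features.n_decoys
        idx = e.features.data.index
        e.features.energy = pd.Series(
            energy[ofs:ofs + n], index=idx, name="total_energy")
        e.features.peptide_energy = pd.Series(
            pep_energy[ofs:ofs + n], index=idx, name="peptide_energy")
        ofs += n
    return SyntheticSuite(
        spec=spec,
        ensembles=ensembles,
        planted_coefficients=pd.Series(beta, index=columns),
        provenance={"generator": "decoyrank.synthetic.generate_feature_suite",
                    "seed": spec.seed},
    )
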