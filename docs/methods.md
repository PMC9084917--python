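# Methods

## Problem and model

Conformational sampling of a 9-mer peptide bound to a class I MHC groove
(e.g. HLA-A\*02:01) produces many candidate models ("decoys") per target.
The conventional selector — lowest computed energy — is unreliable: decoys
separated by a few energy units can differ by several Angstrom of peptide
heavy-atom (HA) RMSD from the experimental structure. `decoyrank`
implements the data-driven alternative: learn a regression function

    predicted HA RMSD  =  f(per-residue structural/energetic features)

from targets whose crystal structures are known, then rank and select
decoys of new targets by *predicted* RMSD instead of energy.

Four function families are supported: ordinary least squares (OLS),
partial least squares (PLS, univariate response), and epsilon-insensitive
support vector regression with no kernel (linSVR) or a Gaussian
radial-basis-function kernel (radSVR).

## RMSD convention

All peptide RMSDs are computed in the *groove frame*: the reference
structure is rigidly superposed onto the decoy using only the Calpha atoms
of MHC heavy-chain residues 1-180 (Kabsch least squares, proper rotations
only, common residue subset if either structure is incomplete); peptide
deviations are then measured with no further fitting on peptide atoms.
Atoms are paired by (residue number, atom name); there is no symmetry
correction for chemically equivalent side-chain atoms (Phe CD1/CD2 etc.) —
a deliberate simplification that slightly overstates side-chain error for
symmetric rings. A C-terminal OXT present in only one structure of a pair
is dropped from the comparison; other unpaired atoms are skipped with a
warning, and more than 10% unpaired in an atom class is an error.

Reported classes: Calpha, heavy (all non-hydrogen), backbone (N, CA, C, O,
OXT), side chain (heavy minus backbone), globally and per peptide position
1-9. The per-position values satisfy the exact aggregation identity
`ha_rmsd^2 * n = sum_p ha_p^2 * n_p`, which the tests verify to 1e-9.

## Solvent accessibility

SASA is computed with the Shrake-Rupley method: probe radius 1.4 A
(water), heavy-atom van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80 A
(configurable — radii conventions differ slightly between programs, and
exact numeric parity with any particular scoring suite is not attempted).
Sample points are a deterministic golden-spiral (Fibonacci) set, default
960 points per atom, so results are bit-reproducible with no RNG. Each
atom's point set is additionally rotated by a fixed, index-derived
rotation; this decorrelates quadrature errors across atoms so that summed
areas converge faster (960 vs 4000 points differ by ~0.1% on fixture
complexes). Hydrophobic SASA sums atoms whose element passes a
configurable predicate (default: carbon and sulfur). SASA is evaluated in
the bound state (peptide in groove) because the features describe the
peptide's solvent exposure as presented.

## Feature pipeline

Per-decoy, per-residue score tables (Rosetta-style or generic CSV) are
joined with computed SASA/hSASA into one row per decoy with columns
`p{1..9}_{term}`, position-major, terms alphabetical within a position.
Filtering is rule-based rather than tied to any fixed term list: columns named on an a-priori exclusion list (residue-identity-specific
terms such as aromatic ring planarity) are removed regardless of variance,
and zero-variance columns are removed. Totals ("total energy", "peptide
energy") are carried as metadata only and are never predictor features.

Scaling centers each column and divides by its *sample* standard deviation
(n-1 denominator, the R convention). By default the scaler is fitted on
the training rows only and applied unchanged to held-out rows (no
leakage); `decoyrank train --scale-before-split` instead fits it on the full
matrix before splitting, reproducing the scale-then-partition order some
workflows use. The 80/20
train/test split is seeded and, with `stratify_bins > 1` (default 10),
stratified on target quantiles with largest-remainder allocation so the
train and test RMSD distributions are comparable.

## Regression and model selection

* **OLS** — `numpy.linalg.lstsq`; rank-deficient designs get the
  minimum-norm pseudo-inverse solution with a warning (feature counts can
  plausibly exceed effective rank).
* **PLS** — scikit-learn's NIPALS implementation (for a univariate
  response this coincides with SIMPLS); the fitted predictor is stored as
  an explicit affine map. Default 10 components; `ncomp > rank(X)` is an
  error. With `ncomp = rank(X)` predictions equal OLS (tested to 1e-8).
* **SVR** — the standard epsilon-insensitive dual problem, tolerance 1e-4.
  The RBF kernel always uses libsvm's SMO. The linear kernel uses libsvm
  up to 1000 training rows; above that it switches to liblinear's dual
  coordinate descent on the mean-centered response (libsvm's SMO needs
  >2e7 iterations on linear-kernel problems at a few thousand rows). In
  the liblinear regime the intercept is the training response mean — exact
  in the noiseless limit, and irrelevant to ranking/selection, which are
  invariant to constant offsets. Epsilon defaults to 0.1 (the libsvm
  convention; the choice is exposed everywhere). Non-convergence within
  the iteration cap (1e7) is a recorded missing grid cell, not a fatal
  error.

Hyperparameters come from a seeded k-fold (default 10) grid search on
integer-decade lattices: linSVR C from 1e-8 to 1e8; radSVR C from 1e-4 to
1e10 crossed with gamma from 1e-11 to 1e2. The gamma grid is deliberately
capped at 1e2 even where RMSE might still decrease, on overfitting
grounds. Fold assignment is a named RNG stream shared by every grid point
and model kind, so comparisons are paired. Exact RMSE ties (within 1e-12)
break to the smallest C, then the smallest gamma — prefer the simpler
model.

A diagnostic (`flag_prediction_collapse`) warns when more than 20% of
predictions fall within +/-0.05 A of a single value while actual RMSDs
span over 1 A — the characteristic RBF-SVR overfitting pathology in which
many decoys receive one pinned prediction regardless of quality.

Models serialize to versioned JSON (schema, columns, scaler, parameters,
training metadata) and round-trip to bitwise-identical predictions.

## Selection and evaluation

Decoys are ranked 1..N (1 = best) by ascending criterion — true HA RMSD,
total energy, peptide energy, or model prediction — with average ranks for
ties. Spearman rank correlation (tie-aware) quantifies agreement with the
true ranking; a constant criterion (all decoys equivalent, e.g. sampling
tightly clustered around one conformation) yields NA with a warning rather
than an error. Selection is the argmin of the criterion with a lexical
decoy-id tie-break.

Method comparisons across targets use paired tests on per-target selected
RMSDs: Wilcoxon matched-pairs signed-rank (zero differences dropped; exact
null for n <= 25 without tied magnitudes, tie-corrected normal
approximation otherwise) and the paired t test. One-tailed alternatives
test that the newer method's RMSDs are *smaller*. Identical selections
across two methods are reported as statistic 0, p = 1 (no evidence of a
difference) rather than as a zero-variance error. Error stratification
averages per-position backbone/side-chain/heavy RMSD across targets and
tabulates per-(position, amino acid) heavy-atom means, omitting (not
zeroing) cells backed by fewer than `min_count = 3` peptides.

## Synthetic data generator

The generator exists so every stage is testable without a modeling suite,
crystal structures, or downloads. It defines the study conditions at two
levels:

* **Coordinate level.** `make_toy_complex` builds a stylized extended
  9-mer with all heavy atoms (roughly plausible local geometry, not
  force-field refined) cradled in a 180-residue Calpha-only groove
  scaffold (two walls, a floor) sufficient for groove superposition and
  bound-state SASA. `perturb_decoys` displaces peptide residues with
  3-residue moving-average-smoothed Gaussian vectors (so neighbors move
  together), an optional per-position bias (to emulate the empirically
  hardest-to-model central bulge), a per-decoy log-normal overall scale,
  and small per-atom jitter; the groove is untouched. Achieved RMSDs are
  always *measured* through the geometry module, never inferred from the
  perturbation magnitude.
* **Feature level.** `generate_feature_suite` draws decoy feature rows
  from a correlated Gaussian around target-specific means and plants a
  known map from features to true HA RMSD: linear (10 informative
  columns) or quadratic (kernel-advantage scenarios). Defaults: 40 targets
  x 200 decoys; target mean RMSDs log-normal (median 1.5 A, sigma 0.35)
  clipped to 0.5-3.5 A, matching the span such decoy ensembles exhibit;
  within-target variance 0.30 A^2 (the sampling-breadth knob; its units
  are A^2 of HA RMSD); residual noise sd 0.15 A; RMSD clipped at zero.
  The "energy" channel is a closed-form blend of the standardized true
  RMSD with an independent noise channel hitting any requested
  energy-RMSD correlation within +/-0.05 (default 0 — energy carries no
  information about quality, the regime that motivates learned
  selection). Per-target RNG streams are keyed (seed, target index), so
  adding targets never changes existing ones, and every suite carries its
  spec + seed; regeneration is bit-identical.

What the generator does **not** emulate: physically realistic
conformational sampling, Rosetta score-term distributions, inter-feature
structure specific to any energy function, or peptide-sequence-dependent
difficulty. Passing tests therefore demonstrate the correctness and power
of the *pipeline* under known ground truth — not modeling accuracy on real
peptide-MHC ensembles, which requires real decoys and crystal structures.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end benchmark at
40 targets x 200 decoys (8000 rows, 45 columns) with linSVR at C = 1,
epsilon = 0.1 — sizes chosen so the whole battery completes in minutes on
one CPU while leaving the qualitative conclusions (predicted-vs-true
R^2 > 0.8, energy R^2 ~ 0, near-oracle selection, Wilcoxon p << 0.05)
with wide margins. Oracle tolerances: rigid-motion recovery and RMSD
identities to 1e-9; scaling idempotence to 1e-12; closed-form SASA (sphere
and two-sphere cap) to 1% at 960 points; noiseless coefficient recovery to
1e-2 (SVR) and 1e-8 (OLS).

## Known limitations

* Trained functions are system-specific by construction: a function
  trained on one allele/peptide-length regime does not transfer, and no
  allele-specific logic is included.
* Only single-model PDB inputs with author numbering (peptide 1-9, groove
  1-180) are supported; mmCIF, assemblies and alt-loc ensembles beyond
  first-conformer selection are out of scope.
* Symmetry-equivalent side-chain atom naming is not canonicalized before
  RMSD pairing.
* The per-residue score-table ingestion expects a consistent term universe
  across decoys of a suite; missing terms are never imputed.
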