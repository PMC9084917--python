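"""RMSD-prediction functions: OLS, PLS, linear SVR and RBF SVR.

Each fitted model stores its own column schema and scaler so that
prediction is a pure function of raw (unscaled) feature rows: columns are
matched by name, centered/scaled with the training-set parameters, then
pushed through the model. Models serialize to versioned JSON and round-trip
to identical predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR, LinearSVR

from .features import FeatureMatrix

__all__ = [
    "SvrHyperparams",
    "RegressionModel",
    "CvResult",
    "fit_ols",
    "fit_pls",
    "fit_svr",
    "fit_model",
    "cross_validate",
    "grid_search",
    "default_grid",
    "predict",
    "save_model",
    "load_model",
    "make_folds",
    "flag_prediction_collapse",
]

MODEL_KINDS = ("ols", "pls", "linsvr", "radsvr")
SCHEMA_VERSION = 1

# Default hyperparameter lattices: integer-decade logarithmic grids.
# linSVR: C from 1e-8 to 1e8; radSVR: C from 1e-4 to 1e10 crossed with
# gamma from 1e-11 to 1e2. Epsilon defaults to 0.1 (libsvm convention).
DEFAULT_EPSILON = 0.1
LINSVR_C_GRID = tuple(10.0 ** k for k in range(-8, 9))
RADSVR_C_GRID = tuple(10.0 ** k for k in range(-4, 11))
RADSVR_GAMMA_GRID = tuple(10.0 ** k for k in range(-11, 3))


@dataclass(frozen=True)
class SvrHyperparams:
    """Epsilon-SVR hyperparameters; gamma only meaningful for the RBF kernel."""

    C: float = 1.0
    gamma: float = 1.0
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class CvResult:
    """Grid-point -> mean k-fold RMSE table from one grid search."""

    table: pd.DataFrame  # columns: C, gamma (NaN for linear), cv_rmse
    k: int
    seed: int


@dataclass
class RegressionModel:
    kind: str
    columns: list[str]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    # linear family (ols, pls, linsvr): explicit weights
    weights: np.ndarray | None = None
    intercept: float = 0.0
    # radsvr: kernel expansion
    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    gamma: float | None = None
    ncomp: int | None = None
    hyperparams: SvrHyperparams | None = None
    training_meta: dict = field(default_factory=dict)

    def predict_scaled(self, x: np.ndarray) -> np.ndarray:
        if self.kind in ("ols", "pls", "linsvr"):
            return x @ self.weights + self.intercept
        d2 = (
            np.sum(x * x, axis=1)[:, None]
            + np.sum(self.support_vectors * self.support_vectors, axis=1)[None, :]
            - 2.0 * x @ self.support_vectors.T
        )
        k = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return k @ self.dual_coef + self.intercept


def _scaler_from_matrix(x: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled design matrix plus the scaler actually used.

    If the matrix was already scaled upstream, reuse its stored parameters;
    otherwise fit mean/sample-sd here.
    """
    if x.scaling is not None:
        mean = x.scaling.mean[x.data.columns].to_numpy()
        sd = x.scaling.sd[x.data.columns].to_numpy()
        return x.data.to_numpy(), mean, sd
    mean = x.data.mean().to_numpy()
    sd = x.data.std(ddof=1).to_numpy()
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("zero/invalid column sd; run filter_terms first")
    return (x.data.to_numpy() - mean) / sd, mean, sd


def _design(x, y=None):
    """Accept a FeatureMatrix (target optional) or plain arrays."""
    if isinstance(x, FeatureMatrix):
        xs, mean, sd = _scaler_from_matrix(x)
        cols = list(x.data.columns)
        if y is None:
            if x.target is None:
                raise ValueError("no target column available")
            y = x.target.to_numpy()
        else:
            y = np.asarray(y, dtype=float)
        return xs, np.asarray(y, dtype=float), cols, mean, sd
    x = np.asarray(x, dtype=float)
    if y is None:
        raise ValueError("y required with a plain array")
    cols = [f"x{i}" for i in range(x.shape[1])]
    return x, np.asarray(y, dtype=float), cols, np.zeros(x.shape[1]), np.ones(x.shape[1])


def fit_ols(x, y=None, *, seed: int | None = None) -> RegressionModel:
    """Ordinary least squares with intercept; min-norm solution if rank
    deficient (with warning)."""
    xs, yv, cols, mean, sd = _design(x, y)
    a = np.column_stack([xs, np.ones(len(xs))])
    sol, _, rank, _ = np.linalg.lstsq(a, yv, rcond=None)
    if rank < a.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {a.shape[1]}); "
            "minimum-norm pseudo-inverse solution", stacklevel=2,
        )
    return RegressionModel(
        kind="ols", columns=cols, scaler_mean=mean, scaler_sd=sd,
        weights=sol[:-1], intercept=float(sol[-1]),
        training_meta={"n": len(yv), "rank": int(rank), "seed": seed},
    )


def fit_pls(x, y=None, ncomp: int = 10, *, seed: int | None = None) -> RegressionModel:
    """Univariate-response partial least squares (NIPALS with deflation).

    The fitted model is a linear predictor, stored as explicit weights.
    """
    xs, yv, cols, mean, sd = _design(x, y)
    rank = np.linalg.matrix_rank(xs - xs.mean(axis=0))
    if ncomp > rank:
        raise ValueError(f"ncomp {ncomp} exceeds design rank {rank}")
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(xs, yv)
    # fold sklearn's internal x-centering into an explicit affine form
    weights = pls.coef_.ravel()
    intercept = float(
        np.asarray(pls.intercept_).ravel()[0] - pls._x_mean @ weights
    )
    return RegressionModel(
        kind="pls", columns=cols, scaler_mean=mean, scaler_sd=sd,
        weights=weights, intercept=intercept, ncomp=ncomp,
        training_meta={"n": len(yv), "rank": int(rank), "seed": seed},
    )


# Above this many rows the linear kernel switches from libsvm's SMO to
# liblinear's dual coordinate descent (mean-centered response), which scales
# far better; the intercept is then the training-set response mean. Rankings
# are unchanged by any constant offset, so decoy selection is unaffected.
LINEAR_SOLVER_SWITCH_N = 1000


def fit_svr(
    x, y=None, kernel: str = "linear",
    hp: SvrHyperparams = SvrHyperparams(),
    *, seed: int | None = None, max_iter: int = 10_000_000,
) -> RegressionModel:
    """Epsilon-insensitive SVR (dual SMO/coordinate-descent, tolerance 1e-4).

    The linear kernel yields an explicit weight vector; the RBF kernel
    stores support vectors and dual coefficients. Non-convergence within
    the iteration cap raises RuntimeError (grid search records such cells
    as missing).
    """
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"unknown kernel {kernel!r}")
    xs, yv, cols, mean, sd = _design(x, y)
    kind = "linsvr" if kernel == "linear" else "radsvr"
    if kernel == "linear" and len(yv) > LINEAR_SOLVER_SWITCH_N:
        y_mean = float(yv.mean())
        solver = LinearSVR(
            C=hp.C, epsilon=hp.epsilon, loss="epsilon_insensitive",
            fit_intercept=False, tol=1e-4, dual=True,
            max_iter=min(max_iter, 50_000), random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                solver.fit(xs, yv - y_mean)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"linear SVR solver did not converge (C={hp.C:g}, "
                    f"n={len(yv)})"
                ) from exc
        return RegressionModel(
            kind=kind, columns=cols, scaler_mean=mean, scaler_sd=sd,
            weights=np.asarray(solver.coef_).ravel(),
            intercept=y_mean,
            hyperparams=hp,
            training_meta={"n": len(yv), "solver": "liblinear", "seed": seed},
        )
    svr = SVR(
        kernel=kernel, C=hp.C, epsilon=hp.epsilon,
        gamma=hp.gamma if kernel == "rbf" else "scale",
        tol=1e-4, max_iter=max_iter, cache_size=200,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svr.fit(xs, yv)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"SVR solver did not converge within {max_iter} iterations "
                f"(C={hp.C:g})"
            ) from exc
    meta = {"n": len(yv), "n_support": int(svr.support_.size),
            "solver": "libsvm", "seed": seed}
    if kernel == "linear":
        return RegressionModel(
            kind=kind, columns=cols, scaler_mean=mean, scaler_sd=sd,
            weights=np.asarray(svr.coef_).ravel(),
            intercept=float(np.asarray(svr.intercept_).ravel()[0]),
            hyperparams=hp, training_meta=meta,
        )
    return RegressionModel(
        kind=kind, columns=cols, scaler_mean=mean, scaler_sd=sd,
        support_vectors=svr.support_vectors_.copy(),
        dual_coef=np.asarray(svr.dual_coef_).ravel(),
        gamma=float(hp.gamma),
        intercept=float(np.asarray(svr.intercept_).ravel()[0]),
        hyperparams=hp, training_meta=meta,
    )


def fit_model(
    kind: str, x, y=None, *,
    hp: SvrHyperparams | None = None, ncomp: int = 10,
    seed: int | None = None,
) -> RegressionModel:
    """Dispatch on model kind (ols | pls | linsvr | radsvr)."""
    if kind == "ols":
        return fit_ols(x, y, seed=seed)
    if kind == "pls":
        return fit_pls(x, y, ncomp=ncomp, seed=seed)
    if kind == "linsvr":
        return fit_svr(x, y, "linear", hp or SvrHyperparams(), seed=seed)
    if kind == "radsvr":
        return fit_svr(x, y, "rbf", hp or SvrHyperparams(), seed=seed)
    raise ValueError(f"unsupported model kind {kind!r}")


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Fold labels 0..k-1: shuffled indices taken modulo k.

    A named, seeded stream so every grid point and model kind sees the same
    folds (paired comparisons stay paired).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng([seed, 0xF01D])
    labels = np.empty(n, dtype=int)
    labels[rng.permutation(n)] = np.arange(n) % k
    counts = np.bincount(labels, minlength=k)
    if counts.min() < 2:
        raise ValueError(f"fold with < 2 rows (n={n}, k={k})")
    return labels


def cross_validate(
    kind: str, x, y=None, *,
    hp: SvrHyperparams | None = None, ncomp: int = 10,
    k: int = 10, seed: int = 0,
) -> float:
    """Mean over k seeded folds of the held-out RMSE."""
    xs, yv, cols, mean, sd = _design(x, y)
    folds = make_folds(len(yv), k, seed)
    rmses = []
    for f in range(k):
        tr = folds != f
        te = ~tr
        model = fit_model(kind, xs[tr], yv[tr], hp=hp, ncomp=ncomp, seed=seed)
        pred = model.predict_scaled(xs[te])
        rmses.append(float(np.sqrt(np.mean((pred - yv[te]) ** 2))))
    return float(np.mean(rmses))


def default_grid(kind: str, epsilon: float = DEFAULT_EPSILON) -> list[SvrHyperparams]:
    if kind == "linsvr":
        return [SvrHyperparams(C=c, epsilon=epsilon) for c in LINSVR_C_GRID]
    if kind == "radsvr":
        return [
            SvrHyperparams(C=c, gamma=g, epsilon=epsilon)
            for c in RADSVR_C_GRID for g in RADSVR_GAMMA_GRID
        ]
    raise ValueError(f"no default grid for kind {kind!r}")


def grid_search(
    x, y=None, kind: str = "linsvr",
    grid: list[SvrHyperparams] | None = None,
    *, k: int = 10, seed: int = 0,
) -> tuple[SvrHyperparams, CvResult]:
    """Seeded k-fold grid search; argmin of mean CV RMSE.

    Every grid point is evaluated on identical folds. Ties (within 1e-12)
    break to the smallest C, then the smallest gamma — prefer the simpler
    model. Solver non-convergence at extreme C leaves a missing (NaN) cell
    rather than aborting the search.
    """
    if grid is None:
        grid = default_grid(kind)
    if not grid:
        raise ValueError("empty grid")
    rows = []
    for hp in grid:
        try:
            rmse = cross_validate(kind, x, y, hp=hp, k=k, seed=seed)
        except RuntimeError as exc:
            warnings.warn(f"grid cell skipped: {exc}", stacklevel=2)
            rmse = np.nan
        rows.append(
            {"C": hp.C, "gamma": hp.gamma if kind == "radsvr" else np.nan,
             "epsilon": hp.epsilon, "cv_rmse": rmse}
        )
    table = pd.DataFrame(rows)
    if table["cv_rmse"].isna().all():
        raise RuntimeError("no grid cell converged")
    best_rmse = table["cv_rmse"].min()
    ties = table[np.abs(table["cv_rmse"] - best_rmse) <= 1e-12]
    ties = ties.sort_values(["C", "gamma"], kind="stable", na_position="last")
    row = ties.iloc[0]
    best = SvrHyperparams(
        C=float(row["C"]),
        gamma=float(row["gamma"]) if np.isfinite(row["gamma"]) else 1.0,
        epsilon=float(row["epsilon"]),
    )
    return best, CvResult(table=table, k=k, seed=seed)


def predict(model: RegressionModel, features) -> np.ndarray:
    """Predicted HA RMSD (Angstrom) for raw, unscaled feature rows.

    Columns are matched by name (order-free); missing or unknown columns
    are an error. Pure and deterministic.
    """
    if isinstance(features, FeatureMatrix):
        if features.scaling is not None:
            raise ValueError("predict expects unscaled features")
        df = features.data
    elif isinstance(features, pd.DataFrame):
        df = features
    else:
        arr = np.asarray(features, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        df = pd.DataFrame(arr, columns=model.columns)
    missing = set(model.columns) - set(df.columns)
    if missing:
        raise ValueError(f"missing feature columns: {sorted(missing)[:5]}")
    x = df[model.columns].to_numpy(dtype=float)
    xs = (x - model.scaler_mean) / model.scaler_sd
    return model.predict_scaled(xs)


def flag_prediction_collapse(
    pred: np.ndarray, actual: np.ndarray,
    *, width: float = 0.05, fraction: float = 0.2, span: float = 1.0,
) -> bool:
    """Warn when predictions pile onto one value despite a wide true range.

    An RBF-SVR overfitting pathology: a large share of decoys receives
    (near-)identical predicted RMSD regardless of actual RMSD. Returns True
    (and warns) when > ``fraction`` of predictions fall within +/- ``width``
    of a single value while the actual targets span more than ``span``.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if actual.max() - actual.min() <= span or pred.size == 0:
        return False
    order = np.sort(pred)
    j = np.searchsorted(order, order + 2 * width, side="right")
    max_count = int(np.max(j - np.arange(order.size)))
    if max_count > fraction * pred.size:
        center = order[int(np.argmax(j - np.arange(order.size)))] + width
        warnings.warn(
            f"{max_count}/{pred.size} predictions collapse within "
            f"+/-{width} of {center:.2f} while targets span "
            f"{actual.max() - actual.min():.2f}; possible overfitting",
            stacklevel=2,
        )
        return True
    return False


def _model_to_dict(model: RegressionModel) -> dict:
    def arr(a):
        return None if a is None else np.asarray(a, dtype=float).tolist()

    return {
        "schema_version": SCHEMA_VERSION,
        "kind": model.kind,
        "columns": model.columns,
        "scaler": {"mean": arr(model.scaler_mean), "sd": arr(model.scaler_sd)},
        "weights": arr(model.weights),
        "intercept": model.intercept,
        "support_vectors": arr(model.support_vectors),
        "dual_coef": arr(model.dual_coef),
        "gamma": model.gamma,
        "ncomp": model.ncomp,
        "hyperparams": (
            None if model.hyperparams is None else {
                "C": model.hyperparams.C,
                "gamma": model.hyperparams.gamma,
                "epsilon": model.hyperparams.epsilon,
            }
        ),
        "training_meta": model.training_meta,
    }


def save_model(model: RegressionModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)


def load_model(path) -> RegressionModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    if doc["kind"] not in MODEL_KINDS:
        raise ValueError(f"unsupported model kind {doc['kind']!r}")

    def arr(a):
        return None if a is None else np.asarray(a, dtype=float)

    hp = doc.get("hyperparams")
    return RegressionModel(
        kind=doc["kind"],
        columns=list(doc["columns"]),
        scaler_mean=arr(doc["scaler"]["mean"]),
        scaler_sd=arr(doc["scaler"]["sd"]),
        weights=arr(doc.get("weights")),
        intercept=float(doc.get("intercept", 0.0)),
        support_vectors=arr(doc.get("support_vectors")),
        dual_coef=arr(doc.get("dual_coef")),
        gamma=doc.get("gamma"),
        ncomp=doc.get("ncomp"),
        hyperparams=None if hp is None else SvrHyperparams(**hp),
        training_meta=doc.get("training_meta", {}),
    )
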