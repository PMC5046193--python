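"""Scoring models: fixed-weight Vina, MLR with rotor-penalty grid, and
random forests with OOB-based mtry selection.

The MLR model fixes the rotor-penalty coefficient w6 by a two-stage grid
search (101 candidates over [0, 1] at step 0.01, then 31 candidates over
[0, 0.030] at step 0.001); for each candidate the pose-dependent features
are divided by (1 + w6 * nrot) before ordinary least squares.

Forests follow the published protocol: 500 CART trees per model, one model
per mtry value from 1 to the number of features P, the mtry with lowest
out-of-bag RMSE kept per seed. Across the (default ten) seeds, deployment
mode keeps the seed with lowest OOB RMSE; paper-replication mode keeps the
seed with lowest held-out-set RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .metrics import rmse
from .vina import DEFAULT_WEIGHTS, PKD_PER_KCAL, VinaWeights

__all__ = [
    "stage1_grid",
    "stage2_grid",
    "MLRVinaModel",
    "fit_mlr_vina",
    "TrainProtocol",
    "ForestModel",
    "fit_forest",
    "FixedVinaModel",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def stage1_grid() -> np.ndarray:
    """Stage-1 rotor-penalty candidates: 0.00 to 1.00 at step 0.01 (101)."""
    return np.round(np.arange(0, 101) * 0.01, 2)


def stage2_grid() -> np.ndarray:
    """Stage-2 refinement candidates: 0.000 to 0.030 at step 0.001 (31)."""
    return np.round(np.arange(0, 31) * 0.001, 3)


def _check_features(X, model_name: str, expected: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2D array (n_samples, n_features)")
    if X.shape[1] != expected:
        raise ValueError(
            f"{model_name}: expected {expected} features, got {X.shape[1]}"
        )
    return X


@dataclass
class MLRVinaModel:
    """Linear model on rotor-penalised Vina-term features."""

    w6: float
    coefficients: np.ndarray
    intercept: float
    nrot_index: int
    n_features: int
    feature_order: list[str] | None = None
    selection: str = "cv"
    n_candidates_stage1: int = 0
    n_candidates_stage2: int = 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Divide pose-dependent features by (1 + w6 * nrot); nrot untouched."""
        X = _check_features(X, "MLR::Vina", self.n_features)
        nrot = X[:, self.nrot_index]
        denom = 1.0 + self.w6 * nrot
        Xt = X / denom[:, None]
        Xt[:, self.nrot_index] = nrot
        return Xt

    def predict(self, X) -> np.ndarray:
        Xt = self.transform(X)
        return Xt @ self.coefficients + self.intercept


def _ols(X: np.ndarray, y: np.ndarray, intercept: bool) -> tuple[np.ndarray, float]:
    # least-norm solution for rank-deficient designs
    if intercept:
        A = np.column_stack([X, np.ones(len(X))])
    else:
        A = X
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient design: using least-norm OLS solution")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if intercept:
        return beta[:-1], float(beta[-1])
    return beta, 0.0


def _mlr_transform(X: np.ndarray, w6: float, nrot_index: int) -> np.ndarray:
    nrot = X[:, nrot_index]
    Xt = X / (1.0 + w6 * nrot)[:, None]
    Xt[:, nrot_index] = nrot
    return Xt


def _mlr_criterion(
    X, y, w6, nrot_index, intercept, selection, X_test, y_test, cv_splits
):
    Xt = _mlr_transform(X, w6, nrot_index)
    if selection == "test":
        coef, b0 = _ols(Xt, y, intercept)
        Xt_test = _mlr_transform(X_test, w6, nrot_index)
        return rmse(Xt_test @ coef + b0, y_test)
    if selection == "train":
        coef, b0 = _ols(Xt, y, intercept)
        return rmse(Xt @ coef + b0, y)
    # k-fold cross-validation on the training data (deployment default)
    errs = []
    for tr, va in cv_splits:
        coef, b0 = _ols(Xt[tr], y[tr], intercept)
        errs.append(rmse(Xt[va] @ coef + b0, y[va]))
    return float(np.mean(errs))


def fit_mlr_vina(
    X,
    y,
    *,
    nrot_index: int = -1,
    intercept: bool = True,
    selection: str = "cv",
    X_test=None,
    y_test=None,
    cv_folds: int = 5,
    feature_order: list[str] | None = None,
) -> MLRVinaModel:
    """Two-stage w6 grid search followed by OLS on transformed features.

    ``selection`` picks the grid criterion: "cv" (k-fold RMSE on training
    data; deployment default), "train" (training RMSE) or "test" (RMSE on
    the supplied held-out set; the published benchmarking convention).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2D with one row per y value")
    if selection not in ("cv", "train", "test"):
        raise ValueError(f"unknown selection mode {selection!r}")
    if selection == "test" and (X_test is None or y_test is None):
        raise ValueError("selection='test' requires X_test and y_test")
    nrot_index = nrot_index % X.shape[1]
    if X_test is not None:
        X_test = np.asarray(X_test, dtype=float)
        y_test = np.asarray(y_test, dtype=float)

    cv_splits = None
    if selection == "cv":
        kf = KFold(n_splits=min(cv_folds, len(X)), shuffle=True, random_state=0)
        cv_splits = list(kf.split(X))

    def criterion(w6: float) -> float:
        return _mlr_criterion(
            X, y, w6, nrot_index, intercept, selection, X_test, y_test, cv_splits
        )

    g1 = stage1_grid()
    errs1 = [criterion(w6) for w6 in g1]
    g2 = stage2_grid()
    errs2 = [criterion(w6) for w6 in g2]
    best_w6 = float(g2[int(np.argmin(errs2))])

    Xt = _mlr_transform(X, best_w6, nrot_index)
    coef, b0 = _ols(Xt, y, intercept)
    return MLRVinaModel(
        w6=best_w6,
        coefficients=coef,
        intercept=b0,
        nrot_index=nrot_index,
        n_features=X.shape[1],
        feature_order=feature_order,
        selection=selection,
        n_candidates_stage1=len(errs1),
        n_candidates_stage2=len(errs2),
    )


@dataclass
class TrainProtocol:
    """Forest training protocol knobs.

    ``selection="oob"`` is the deployment default; ``"test"`` reproduces
    the published convention of keeping the seed with the lowest held-out
    RMSE (flagged as test-set selection).
    """

    seeds: list[int] = field(default_factory=lambda: list(range(10)))
    n_trees: int = 500
    mtry_values: list[int] | None = None  # default: 1..P
    selection: str = "oob"
    min_samples_leaf: int = 5


@dataclass
class ForestModel:
    """A fitted random-forest scorer; prediction is the mean over trees."""

    estimator: RandomForestRegressor
    n_trees: int
    mtry: int
    seed: int
    oob_rmse: float
    test_rmse: float | None = None
    n_features: int = 0
    feature_order: list[str] | None = None
    n_mtry_candidates: int = 0

    def predict(self, X) -> np.ndarray:
        X = _check_features(X, "forest", self.n_features)
        return self.estimator.predict(X)


def _oob_rmse(forest: RandomForestRegressor, y: np.ndarray) -> float:
    oob = forest.oob_prediction_
    ok = np.isfinite(oob)
    return rmse(oob[ok], y[ok])


def fit_forest(
    X,
    y,
    protocol: TrainProtocol | None = None,
    *,
    X_test=None,
    y_test=None,
    feature_order: list[str] | None = None,
) -> ForestModel:
    """Fit forests over the mtry grid and seeds, keeping the best.

    Per seed, one forest is grown per mtry value and the mtry with lowest
    OOB RMSE is kept; across seeds the winner follows ``protocol.selection``.
    """
    protocol = protocol or TrainProtocol()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1 or len(X) == 0:
        raise ValueError("X must be a nonempty 2D array")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if protocol.selection not in ("oob", "test"):
        raise ValueError(f"unknown selection mode {protocol.selection!r}")
    if protocol.selection == "test" and (X_test is None or y_test is None):
        raise ValueError("selection='test' requires X_test and y_test")

    P = X.shape[1]
    mtry_values = protocol.mtry_values or list(range(1, P + 1))

    best: ForestModel | None = None
    for seed in protocol.seeds:
        seed_best: tuple[float, int, RandomForestRegressor] | None = None
        for mtry in mtry_values:
            if not 1 <= mtry <= P:
                raise ValueError(f"mtry {mtry} outside [1, {P}]")
            forest = RandomForestRegressor(
                n_estimators=protocol.n_trees,
                max_features=mtry,
                min_samples_leaf=protocol.min_samples_leaf,
                bootstrap=True,
                oob_score=True,
                random_state=seed,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                forest.fit(X, y)
            err = _oob_rmse(forest, y)
            if seed_best is None or err < seed_best[0]:
                seed_best = (err, mtry, forest)
        oob_err, mtry, forest = seed_best
        test_err = (
            rmse(forest.predict(np.asarray(X_test, dtype=float)), y_test)
            if X_test is not None
            else None
        )
        candidate = ForestModel(
            estimator=forest,
            n_trees=protocol.n_trees,
            mtry=mtry,
            seed=seed,
            oob_rmse=oob_err,
            test_rmse=test_err,
            n_features=P,
            feature_order=feature_order,
            n_mtry_candidates=len(mtry_values),
        )
        key = candidate.test_rmse if protocol.selection == "test" else candidate.oob_rmse
        best_key = None
        if best is not None:
            best_key = best.test_rmse if protocol.selection == "test" else best.oob_rmse
        if best is None or key < best_key:
            best = candidate
    return best


@dataclass
class FixedVinaModel:
    """Model 1: the published Vina weights, never re-fitted.

    Operates on the single-pose 11-feature layout. For the pose the
    features were extracted from (rank-1 docked or crystal), the intra
    contributions cancel, so the score reduces to the weighted inter terms
    over the rotor penalty, converted to pKd.
    """

    weights: VinaWeights = field(default_factory=lambda: DEFAULT_WEIGHTS)
    n_features: int = 11

    def predict(self, X) -> np.ndarray:
        X = _check_features(X, "Vina", self.n_features)
        inter = X[:, :5]
        nrot = X[:, -1]
        e = (inter @ self.weights.term_weights) / (1.0 + self.weights.w6 * nrot)
        return PKD_PER_KCAL * e


def predict(model, X) -> np.ndarray:
    """Predict pKd for each feature row; validates feature length."""
    return model.predict(X)


def save_model(model, path, *, scheme=None, d_cutoff=None) -> None:
    """Persist a fitted model with its interpretation metadata."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": type(model).__name__,
        "model": model,
        "scheme": scheme,
        "d_cutoff": d_cutoff,
    }
    joblib.dump(payload, path)


def load_model(path):
    """Load a model saved by :func:`save_model`; returns (model, metadata)."""
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    meta = {k: payload[k] for k in ("kind", "scheme", "d_cutoff")}
    return payload["model"], meta
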