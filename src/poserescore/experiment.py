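"""End-to-end workflows: featurization tables and the scheme/model matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import EvalReport, evaluate, pose_rmsds
from .models import (
    FixedVinaModel,
    TrainProtocol,
    fit_forest,
    fit_mlr_vina,
)
from .schemes import (
    TRAIN_ONLY_SCHEMES,
    SchemeSpec,
    assemble_features,
    feature_names,
)

__all__ = [
    "MODEL_FEATURE_SETS",
    "featurize_complexes",
    "feature_table",
    "train_model",
    "run_experiment_matrix",
]

#: feature set used by each model (models 1-3 use Vina terms, model 4 adds contacts)
MODEL_FEATURE_SETS = {
    "vina": "vina11",
    "mlr": "vina11",
    "rf-vina": "vina11",
    "rf-vinaelem": "vinaelem47",
}


def featurize_complexes(complexes, spec: SchemeSpec, d_cutoff: float = 12.0):
    """Assemble features for every complex; returns (X, y, ids).

    ``y`` entries are NaN for complexes without a measured affinity.
    """
    X, y, ids = [], [], []
    for receptor, pose_set in complexes:
        fv = assemble_features(pose_set, spec, receptor, d_cutoff)
        X.append(fv.values)
        aff = pose_set.measured_affinity
        y.append(float("nan") if aff is None else float(aff))
        ids.append(pose_set.ligand_id)
    return np.array(X), np.array(y), ids


def feature_table(complexes, spec: SchemeSpec, d_cutoff: float = 12.0) -> pd.DataFrame:
    """Tabular feature file: complex_id, scheme, named feature columns, affinity."""
    X, y, ids = featurize_complexes(complexes, spec, d_cutoff)
    df = pd.DataFrame(X, columns=feature_names(spec))
    df.insert(0, "scheme", spec.scheme_id)
    df.insert(0, "complex_id", ids)
    df["affinity"] = y
    return df


def train_model(
    model: str,
    X_train,
    y_train,
    *,
    X_test=None,
    y_test=None,
    selection: str | None = None,
    protocol: TrainProtocol | None = None,
):
    """Fit one of the four models on a feature matrix."""
    if model == "vina":
        return FixedVinaModel(n_features=np.asarray(X_train).shape[1])
    if model == "mlr":
        return fit_mlr_vina(
            X_train,
            y_train,
            selection=selection or "cv",
            X_test=X_test,
            y_test=y_test,
        )
    if model in ("rf-vina", "rf-vinaelem"):
        protocol = protocol or TrainProtocol()
        if selection:
            protocol.selection = selection
        return fit_forest(X_train, y_train, protocol, X_test=X_test, y_test=y_test)
    raise ValueError(f"unknown model {model!r}")


def _check_test_scheme(scheme_id: int) -> None:
    if scheme_id in TRAIN_ONLY_SCHEMES:
        raise ValueError(
            f"scheme {scheme_id} cannot be used for testing purpose "
            "(test-time inputs lack the RMSD / measured affinity it needs)"
        )


def run_experiment_matrix(
    train_complexes,
    test_complexes,
    scheme_pairs: list[tuple[int, int]],
    models: list[str],
    *,
    protocol: TrainProtocol | None = None,
    mlr_selection: str = "cv",
    d_cutoff: float = 12.0,
    include_pose_rmsds: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """One evaluation row per (model, train scheme, test scheme).

    The fixed Vina model is never re-fitted, so its rows are identical
    across training schemes (and it only applies to single-pose layouts).
    Returns (summary table, {row key -> EvalReport}).
    """
    for _, test_scheme in scheme_pairs:
        _check_test_scheme(test_scheme)

    rows, reports = [], {}
    feature_cache: dict = {}

    def features(complexes, tag, scheme_id, fs):
        key = (tag, scheme_id, fs)
        if key not in feature_cache:
            feature_cache[key] = featurize_complexes(
                complexes, SchemeSpec(scheme_id, fs), d_cutoff
            )
        return feature_cache[key]

    for model in models:
        fs = MODEL_FEATURE_SETS[model]
        for train_scheme, test_scheme in scheme_pairs:
            if model == "vina" and (train_scheme in (5, 6) or test_scheme in (5, 6)):
                continue  # fixed Vina operates on single-pose features only
            X_tr, y_tr, _ = features(train_complexes, "train", train_scheme, fs)
            X_te, y_te, ids = features(test_complexes, "test", test_scheme, fs)
            if X_tr.shape[1] != X_te.shape[1]:
                raise ValueError(
                    f"train scheme {train_scheme} and test scheme {test_scheme} "
                    f"produce incompatible feature lengths "
                    f"({X_tr.shape[1]} vs {X_te.shape[1]})"
                )
            fitted = train_model(
                model,
                X_tr,
                y_tr,
                X_test=X_te,
                y_test=y_te,
                selection=mlr_selection if model == "mlr" else None,
                protocol=protocol,
            )
            pred = fitted.predict(X_te)
            rmsds = None
            if include_pose_rmsds:
                rmsds = []
                for _, ps in test_complexes:
                    try:
                        per_pose = pose_rmsds(ps)
                        rmsds.append(per_pose[0] if per_pose else None)
                    except ValueError:
                        rmsds.append(None)
            report = evaluate(ids, pred, y_te, scored_pose_rmsds=rmsds)
            key = (model, train_scheme, test_scheme)
            reports[key] = report
            rows.append(
                {
                    "model": model,
                    "train_scheme": train_scheme,
                    "test_scheme": test_scheme,
                    "rmse": report.rmse,
                    "sd": report.sd,
                    "rp": report.rp,
                    "rs": report.rs,
                }
            )
    return pd.DataFrame(rows), reports
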