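"""Property-model training/evaluation harness and feature informativeness.

``nested_cv_svr`` evaluates a radial-basis support-vector regressor by
nested cross-validation: an outer k-fold split yields held-out validation
sets that never influence hyperparameter choice, and within each outer
training partition a grid search over (C, epsilon) is scored by inner k-fold
CV.  Accuracy metrics (R^2, MAE, RMSE) are computed on the pooled
out-of-fold predictions, each sample being predicted exactly once.

Feature informativeness is reported as the mutual information between a
feature and the target, MI(X; Y) = H(Y) - H(Y|X), estimated with the
k-nearest-neighbour continuous estimator (k=3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_regression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

__all__ = ["CVReport", "nested_cv_svr", "mutual_information", "mi_heatmap",
           "DEFAULT_C_GRID", "DEFAULT_EPS_GRID"]

DEFAULT_C_GRID = (1.0, 10.0, 100.0, 1000.0)
DEFAULT_EPS_GRID = (0.1, 0.5, 1.0, 5.0)


@dataclass
class CVReport:
    """Nested cross-validation results.

    ``oof_pred`` holds the out-of-fold prediction of every sample aligned to
    the input order; pooled metrics are recomputable from it.
    """

    r2: float
    mae: float
    rmse: float
    fold_r2: list[float]
    fold_mae: list[float]
    fold_rmse: list[float]
    oof_pred: np.ndarray
    fold_of_sample: np.ndarray
    chosen_params: list[dict]

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "mae": self.mae,
            "rmse": self.rmse,
            "fold_r2": self.fold_r2,
            "fold_mae": self.fold_mae,
            "fold_rmse": self.fold_rmse,
            "chosen_params": self.chosen_params,
        }


def nested_cv_svr(
    X: np.ndarray | None,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    eps_grid: Sequence[float] = DEFAULT_EPS_GRID,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    embed_fn: Callable | None = None,
) -> CVReport:
    """Nested-CV evaluation of an RBF support-vector regressor.

    ``embed_fn(train_idx, test_idx) -> (X_train, X_test)`` lets the caller
    recompute features (e.g. retrain the embedder) per outer fold so the
    validation molecules never enter the feature construction; when omitted,
    a precomputed ``X`` is indexed directly (convenience mode — the features
    themselves may then leak across folds if they were fit on all samples).
    """
    y = np.asarray(y, dtype=float)
    N = y.size
    if N < outer_folds:
        raise ValueError(f"need at least outer_folds={outer_folds} samples, got {N}")
    if not len(C_grid) or not len(eps_grid):
        raise ValueError("hyperparameter grids must be non-empty")
    if X is None and embed_fn is None:
        raise ValueError("provide X or embed_fn")
    if np.ptp(y) == 0:
        warnings.warn("constant target: R^2 is undefined (NaN)")
    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    oof = np.full(N, np.nan)
    fold_of = np.full(N, -1, dtype=int)
    fold_r2, fold_mae, fold_rmse, chosen = [], [], [], []
    grid = {"C": list(C_grid), "epsilon": list(eps_grid)}
    for f, (tr, te) in enumerate(outer.split(np.zeros(N))):
        if embed_fn is not None:
            X_tr, X_te = embed_fn(tr, te)
        else:
            X_tr, X_te = np.asarray(X)[tr], np.asarray(X)[te]
        inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)
        search = GridSearchCV(SVR(kernel="rbf"), grid, cv=inner, scoring="r2", n_jobs=1)
        search.fit(X_tr, y[tr])
        pred = search.best_estimator_.predict(X_te)
        oof[te] = pred
        fold_of[te] = f
        chosen.append(dict(search.best_params_))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_r2.append(float(r2_score(y[te], pred)) if np.ptp(y[te]) > 0 else float("nan"))
        fold_mae.append(float(mean_absolute_error(y[te], pred)))
        fold_rmse.append(float(np.sqrt(mean_squared_error(y[te], pred))))
    pooled_r2 = float(r2_score(y, oof)) if np.ptp(y) > 0 else float("nan")
    return CVReport(
        r2=pooled_r2,
        mae=float(mean_absolute_error(y, oof)),
        rmse=float(np.sqrt(mean_squared_error(y, oof))),
        fold_r2=fold_r2,
        fold_mae=fold_mae,
        fold_rmse=fold_rmse,
        oof_pred=oof,
        fold_of_sample=fold_of,
        chosen_params=chosen,
    )


def mutual_information(
    x: np.ndarray, y: np.ndarray, n_neighbors: int = 3, seed: int = 0
) -> float:
    """MI (nats) between one feature and the target, kNN estimator (k=3)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must align")
    if x.size < 20:
        raise ValueError("need at least 20 samples for the kNN MI estimator")
    if np.ptp(x) == 0:
        return 0.0
    mi = mutual_info_regression(
        x[:, None], y, n_neighbors=n_neighbors, random_state=seed
    )
    return float(mi[0])


def mi_heatmap(
    X: np.ndarray,
    y_by_dataset: dict[str, np.ndarray],
    n_subsample: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """MI of every feature against every dataset's target.

    Rows are datasets, columns are features.  Sample sizes are equalized by
    subsampling ``n_subsample`` molecules per dataset (default: the smallest
    dataset size) so MI magnitudes are comparable across datasets.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    sizes = {k: np.asarray(v).size for k, v in y_by_dataset.items()}
    n = min(sizes.values()) if n_subsample is None else n_subsample
    rows = {}
    for name, y in y_by_dataset.items():
        y = np.asarray(y, dtype=float)
        idx = rng.choice(y.size, size=min(n, y.size), replace=False)
        rows[name] = [
            mutual_information(X[idx, j], y[idx], seed=seed) for j in range(X.shape[1])
        ]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"c{j+1}" for j in range(X.shape[1])])
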