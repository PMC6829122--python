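"""Support vector regression and tree-ensemble learners.

Thin adapters over scikit-learn estimators so that SVR (linear, polynomial,
radial basis function), Random Forest and Gradient Tree Boosting honor the
benchmark's uniform fit/predict contract, expose per-marker importances
where the algorithm produces them, and carry documented default
hyperparameter grids (one to five tuned hyperparameters per algorithm;
rrBLUP, BRR and BL take none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.svm import SVR

from .datatypes import AlignmentError, GenotypeMatrix

__all__ = [
    "HyperGrid",
    "SklearnStyleFit",
    "fit_svr",
    "fit_tree_ensemble",
    "default_hypergrid",
    "KNOWN_ALGORITHMS",
]

KNOWN_ALGORITHMS = (
    "rrBLUP",
    "BRR",
    "BA",
    "BB",
    "BL",
    "SVR_lin",
    "SVR_poly",
    "SVR_rbf",
    "RF",
    "GTB",
    "ANN",
    "CNN",
)


@dataclass
class HyperGrid:
    """Named hyperparameter -> candidate values for one algorithm."""

    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.grid.items():
            if len(values) == 0:
                raise ValueError(f"empty candidate list for {name!r}")

    def combinations(self) -> list[dict[str, Any]]:
        """Cartesian product of the candidate lists."""
        combos: list[dict[str, Any]] = [{}]
        for name, values in self.grid.items():
            combos = [{**c, name: v} for c in combos for v in values]
        return combos

    @property
    def is_empty(self) -> bool:
        return len(self.grid) == 0


@dataclass
class SklearnStyleFit:
    """A trained scikit-learn-backed predictor under the common contract."""

    algorithm: str
    hyperparameters: dict[str, Any]
    estimator: Any
    n_markers: int
    importances: np.ndarray | None = None

    def predict(self, G_new) -> np.ndarray:
        X = np.asarray(
            G_new.X() if isinstance(G_new, GenotypeMatrix) else G_new, dtype=float
        )
        if X.shape[1] != self.n_markers:
            raise AlignmentError(
                f"marker mismatch: fit expects {self.n_markers}, got {X.shape[1]}"
            )
        return np.asarray(self.estimator.predict(X), dtype=float)

    @property
    def marker_scores(self) -> np.ndarray | None:
        return self.importances


def _as_xy(G_train, y_train):
    X = np.asarray(
        G_train.X() if isinstance(G_train, GenotypeMatrix) else G_train, dtype=float
    )
    y = np.asarray(y_train, dtype=float)
    if y.shape != (X.shape[0],):
        raise AlignmentError("y_train length does not match G_train rows")
    return X, y


def fit_svr(
    G_train,
    y_train,
    kernel: str = "lin",
    C: float = 1.0,
    gamma: float = 1e-3,
    degree: int = 2,
    epsilon: float = 0.1,
) -> SklearnStyleFit:
    """Epsilon-insensitive support vector regression.

    ``kernel`` is one of ``lin`` / ``poly`` / ``rbf``; ``degree`` applies to
    the polynomial kernel only.  Deterministic given data and settings.
    """
    if kernel not in ("lin", "poly", "rbf"):
        raise ValueError("kernel must be 'lin', 'poly' or 'rbf'")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    if kernel == "poly" and degree < 2:
        raise ValueError("polynomial degree must be >= 2")
    X, y = _as_xy(G_train, y_train)
    sk_kernel = {"lin": "linear", "poly": "poly", "rbf": "rbf"}[kernel]
    est = SVR(kernel=sk_kernel, C=C, gamma=gamma, degree=degree, epsilon=epsilon)
    est.fit(X, y)
    return SklearnStyleFit(
        algorithm=f"SVR_{kernel}",
        hyperparameters={"C": C, "gamma": gamma, "degree": degree, "epsilon": epsilon},
        estimator=est,
        n_markers=X.shape[1],
    )


def fit_tree_ensemble(
    G_train,
    y_train,
    family: str = "RF",
    max_depth: int = 5,
    max_features: float = 0.5,
    n_trees: int = 500,
    learning_rate: float = 0.1,
    seed: int | None = None,
) -> SklearnStyleFit:
    """Random Forest (bagged trees) or Gradient Tree Boosting.

    Seed-deterministic; exposes impurity-based marker importances (which
    scikit-learn normalizes to sum to 1).
    """
    if family not in ("RF", "GTB"):
        raise ValueError("family must be 'RF' or 'GTB'")
    if max_depth is not None and max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y = _as_xy(G_train, y_train)
    if family == "RF":
        est = RandomForestRegressor(
            n_estimators=n_trees,
            max_depth=max_depth,
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )
        hp = {"max_depth": max_depth, "max_features": max_features, "n_trees": n_trees}
    else:
        est = GradientBoostingRegressor(
            n_estimators=n_trees,
            max_depth=max_depth,
            max_features=max_features,
            learning_rate=learning_rate,
            random_state=seed,
        )
        hp = {
            "max_depth": max_depth,
            "max_features": max_features,
            "n_trees": n_trees,
            "learning_rate": learning_rate,
        }
    est.fit(X, y)
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return SklearnStyleFit(
        algorithm=family,
        hyperparameters=hp,
        estimator=est,
        n_markers=X.shape[1],
        importances=imp,
    )


# Nine MLP architectures: one to three hidden layers, 5-100 nodes each.
ANN_ARCHITECTURES: list[tuple[int, ...]] = [
    (5,),
    (50,),
    (100,),
    (5, 5),
    (50, 50),
    (100, 100),
    (5, 5, 5),
    (50, 50, 50),
    (100, 100, 100),
]


def default_hypergrid(algorithm: str) -> HyperGrid:
    """Documented default search grid for one algorithm.

    rrBLUP, BRR and BL need no user-set hyperparameters (their regularization
    is estimated from the data) and get an empty grid.  Tree grids favor
    shallow depths, which tend to win for genomic prediction.  All grids are
    conventions and fully overridable via configuration.
    """
    if algorithm in ("rrBLUP", "BRR", "BL"):
        return HyperGrid(algorithm=algorithm, grid={})
    if algorithm in ("BA", "BB"):
        return HyperGrid(algorithm=algorithm, grid={"df": [3.0, 5.0, 10.0]})
    if algorithm == "SVR_lin":
        return HyperGrid(
            algorithm=algorithm,
            grid={"C": [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]},
        )
    if algorithm == "SVR_poly":
        return HyperGrid(
            algorithm=algorithm,
            grid={
                "C": [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3],
                "gamma": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
                "degree": [2, 3],
            },
        )
    if algorithm == "SVR_rbf":
        return HyperGrid(
            algorithm=algorithm,
            grid={
                "C": [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3],
                "gamma": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
            },
        )
    if algorithm == "RF":
        return HyperGrid(
            algorithm=algorithm,
            grid={
                "max_depth": [3, 5, 10, 50],
                "max_features": [0.1, 0.25, 0.5, 0.75, 1.0],
            },
        )
    if algorithm == "GTB":
        return HyperGrid(
            algorithm=algorithm,
            grid={
                "max_depth": [3, 5, 10, 50],
                "max_features": [0.1, 0.25, 0.5, 0.75, 1.0],
                "learning_rate": [0.01, 0.1],
            },
        )
    if algorithm == "ANN":
        return HyperGrid(
            algorithm=algorithm,
            grid={
                "hidden_layer_sizes": list(ANN_ARCHITECTURES),
                "activation": ["relu", "sigmoid"],
                "dropout_rate": [0.10, 0.50],
                "l2_penalty": [0.0, 0.1],
                "learning_rate": [1e-3, 1e-2],
            },
        )
    if algorithm == "CNN":
        return HyperGrid(
            algorithm=algorithm,
            grid={
                "n_filters": [8, 16, 32],
                "kernel_width": [3, 5, 9],
                "dense_width": [16, 32, 64],
                "dropout_rate": [0.10, 0.25, 0.50],
                "learning_rate": [1e-3, 1e-2],
            },
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")
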