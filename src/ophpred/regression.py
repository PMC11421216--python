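"""Regressors over sequence embeddings, with grid-search model selection.

Three families: k-nearest-neighbor regression (Euclidean distance, uniform
or inverse-distance weights), gradient-boosted regression trees (XGBoost),
and the naive median baseline that always predicts the training-label
median — the MAE-optimal constant, which any useful model must beat.
Hyperparameters are selected by seeded k-fold grid search minimizing mean
absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from .embed import EmbeddingMatrix
from .errors import ValidationError

FAMILIES = ("knn", "gbt", "naive_median")


@dataclass(frozen=True)
class RegressorSpec:
    family: str
    hyperparameters: tuple[tuple[str, Any], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown regressor family {self.family!r}")
        hp = dict(self.hyperparameters)
        if self.family == "knn" and hp.get("n_neighbors", 1) < 1:
            raise ValidationError("knn: n_neighbors must be >= 1")

    @classmethod
    def make(cls, family: str, seed: int = 0, **hyperparameters: Any) -> "RegressorSpec":
        return cls(
            family=family,
            hyperparameters=tuple(sorted(hyperparameters.items())),
            seed=seed,
        )

    @property
    def hp(self) -> dict[str, Any]:
        return dict(self.hyperparameters)


@dataclass
class FittedModel:
    spec: RegressorSpec
    embedder_name: str
    train_ids: list[str]
    d: int
    _state: Any = field(repr=False, default=None)

    def predict(self, X: EmbeddingMatrix | np.ndarray) -> np.ndarray:
        A = X.X if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
        if A.size and A.shape[1] != self.d:
            raise ValidationError(
                f"embedding dimension {A.shape[1]} does not match model ({self.d})"
            )
        if A.shape[0] == 0:
            return np.empty(0)
        if self.spec.family == "naive_median":
            return np.full(A.shape[0], self._state)
        return np.asarray(self._state.predict(A), dtype=float)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "FittedModel":
        model = joblib.load(path)
        if not isinstance(model, FittedModel):
            raise ValidationError(f"{path} does not contain a fitted ophpred model")
        return model


def fit(
    spec: RegressorSpec,
    X: EmbeddingMatrix,
    y: Sequence[float],
) -> FittedModel:
    y = np.asarray(y, dtype=float)
    if len(y) != X.X.shape[0]:
        raise ValidationError("fit: X rows and y length differ")
    if len(y) == 0:
        raise ValidationError("fit: empty training set")
    if np.isnan(y).any():
        raise ValidationError("fit: NaN in training labels")
    hp = spec.hp
    if spec.family == "naive_median":
        state: Any = float(np.median(y))
    elif spec.family == "knn":
        n_neighbors = int(hp.get("n_neighbors", 5))
        if len(y) < n_neighbors:
            raise ValidationError(
                f"knn: n={len(y)} training rows < n_neighbors={n_neighbors}"
            )
        state = KNeighborsRegressor(
            n_neighbors=n_neighbors,
            weights=hp.get("weights", "uniform"),
            metric="euclidean",
        ).fit(X.X, y)
    else:  # gbt
        from xgboost import XGBRegressor

        state = XGBRegressor(
            max_depth=int(hp.get("max_depth", 6)),
            n_estimators=int(hp.get("n_estimators", 100)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            random_state=spec.seed,
            n_jobs=1,
            verbosity=0,
        ).fit(X.X, y)
    return FittedModel(
        spec=spec,
        embedder_name=X.embedder_name,
        train_ids=list(X.ids),
        d=X.d,
        _state=state,
    )


def default_knn_grid(seed: int = 0) -> list[RegressorSpec]:
    return [
        RegressorSpec.make("knn", seed=seed, n_neighbors=k, weights=w)
        for k in (1, 3, 5, 10, 20)
        for w in ("uniform", "distance")
    ]


def default_gbt_grid(seed: int = 0) -> list[RegressorSpec]:
    return [
        RegressorSpec.make(
            "gbt", seed=seed, max_depth=d, n_estimators=t, learning_rate=lr
        )
        for d in (3, 6)
        for t in (100, 300)
        for lr in (0.05, 0.1)
    ]


def grid_search(
    grid: Sequence[RegressorSpec],
    X: EmbeddingMatrix,
    y: Sequence[float],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[RegressorSpec, dict[RegressorSpec, float]]:
    """Seeded k-fold grid search minimizing mean absolute validation error.

    Returns the argmin spec (ties broken by grid order) and the full
    spec -> mean-MAE table. Specs infeasible on some fold (e.g. n_neighbors
    larger than the fold's training side) score infinity.
    """
    if not grid:
        raise ValidationError("grid_search: empty grid")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValidationError(f"grid_search: n={n} < n_folds={n_folds}")
    folds = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X.X))
    cv_table: dict[RegressorSpec, float] = {}
    for spec in grid:
        fold_maes = []
        try:
            for train_idx, val_idx in folds:
                sub = EmbeddingMatrix(
                    ids=[X.ids[i] for i in train_idx],
                    X=X.X[train_idx],
                    embedder_name=X.embedder_name,
                )
                model = fit(spec, sub, y[train_idx])
                pred = model.predict(X.X[val_idx])
                fold_maes.append(float(np.mean(np.abs(pred - y[val_idx]))))
            cv_table[spec] = float(np.mean(fold_maes))
        except ValidationError:
            cv_table[spec] = float("inf")
    best = min(grid, key=lambda s: cv_table[s])  # ties: first in grid order
    if cv_table[best] == float("inf"):
        raise ValidationError("grid_search: no feasible spec in grid")
    return best, cv_table


def fit_best(
    grid: Sequence[RegressorSpec],
    X: EmbeddingMatrix,
    y: Sequence[float],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[FittedModel, dict[RegressorSpec, float]]:
    """Grid search then refit the winning spec on the full training set."""
    best, cv_table = grid_search(grid, X, y, n_folds=n_folds, seed=seed)
    return fit(best, X, y), cv_table
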