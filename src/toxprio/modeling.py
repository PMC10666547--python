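"""Random-forest QSAR regression and direct classification.

Two competing predictors are trained on the curated descriptor matrix:

* a regression forest on log10 LC50, whose predictions are thresholded
  into hazard categories in a second step (the conventional two-step
  QSAR route), and
* a classification forest trained directly on the category labels.

Hyperparameters (number of trees, minimum points per leaf) are tuned on
a 2-D grid with 3-fold cross-validation; each tree sees floor(sqrt(p))
candidate variables per split.  Variable importance is measured
out-of-bag (permutation by default, impurity optionally) and variables
contributing more than 1% relative to the largest importance are kept
for the final refit on the full data set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score

from .categorization import ToxicityCategorySchema, assign_ghs, assign_kmeans
from .errors import NotFittedError

__all__ = [
    "HyperparameterGrid",
    "TrainedModel",
    "GridSearchResult",
    "default_regression_grid",
    "default_classification_grid",
    "split_train_test",
    "grid_search",
    "oob_permutation_importance",
    "oob_impurity_importance",
    "select_by_relative_importance",
    "fit_final",
    "predict_lc50",
    "predict_category_direct",
    "two_step_categorize",
    "save_model",
    "load_model",
]

Task = Literal["regression", "classification"]


@dataclass
class HyperparameterGrid:
    """A 2-D grid over forest size and leaf granularity."""

    n_trees: tuple[int, ...]
    min_leaf: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.n_trees or not self.min_leaf:
            raise ValueError("grid axes must be nonempty")
        if min(self.n_trees) < 1 or min(self.min_leaf) < 1:
            raise ValueError("grid values must be >= 1")
        self.n_trees = tuple(int(t) for t in self.n_trees)
        self.min_leaf = tuple(int(m) for m in self.min_leaf)

    def cells(self):
        for t in self.n_trees:
            for m in self.min_leaf:
                yield t, m


def default_regression_grid() -> HyperparameterGrid:
    """Trees 100..1000 (10 log-spaced values), min leaf 1..21 step 2."""
    trees = tuple(int(round(t)) for t in np.geomspace(100, 1000, 10))
    return HyperparameterGrid(n_trees=trees, min_leaf=tuple(range(1, 22, 2)))


def default_classification_grid() -> HyperparameterGrid:
    """Trees 200..2000 and min leaf 1..21, 20 steps per axis."""
    trees = tuple(int(round(t)) for t in np.linspace(200, 2000, 20))
    leaves = tuple(sorted(set(int(round(m)) for m in np.linspace(1, 21, 20))))
    return HyperparameterGrid(n_trees=trees, min_leaf=leaves)


def split_train_test(n: int, frac: float = 0.9, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint covering train/test index split, round(frac*n) train."""
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(round(frac * n))
    if n_train in (0, n):
        raise ValueError(f"degenerate split: {n_train} train of {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _make_forest(task: Task, n_trees: int, min_leaf: int, seed: int,
                 oob: bool = False):
    kw = dict(n_estimators=n_trees, min_samples_leaf=min_leaf,
              max_features="sqrt", bootstrap=True, oob_score=oob,
              random_state=seed, n_jobs=1)
    if task == "regression":
        return RandomForestRegressor(**kw)
    if task == "classification":
        return RandomForestClassifier(**kw)
    raise ValueError(f"unknown task {task!r}")


def _oob_masks(forest, n: int) -> list[np.ndarray]:
    masks = []
    for sample_idx in forest.estimators_samples_:
        m = np.ones(n, dtype=bool)
        m[sample_idx] = False
        masks.append(m)
    return masks


def oob_permutation_importance(forest, X: np.ndarray, y: np.ndarray,
                               seed: int = 0) -> np.ndarray:
    """Out-of-bag permutation importance of each column.

    For every tree, its out-of-bag rows are scored before and after
    permuting one column; the importance of the column is the mean score
    drop over trees (clipped at 0).  Score is accuracy for classifiers
    and negative MSE for regressors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    is_clf = hasattr(forest, "classes_")
    masks = _oob_masks(forest, n)

    def _score(tree, Xo, yo):
        pred = tree.predict(Xo)
        if is_clf:
            return accuracy_score(yo, forest.classes_[pred.astype(int)]
                                  if pred.dtype.kind in "fiu" else pred)
        return -float(np.mean((yo - pred) ** 2))

    drops = np.zeros(p)
    n_used = 0
    for tree, mask in zip(forest.estimators_, masks):
        if not mask.any():
            continue
        Xo, yo = X[mask], y[mask]
        base = _score(tree, Xo, yo)
        perm = rng.permutation(Xo.shape[0])
        for j in range(p):
            col = Xo[:, j].copy()
            Xo[:, j] = col[perm]
            drops[j] += base - _score(tree, Xo, yo)
            Xo[:, j] = col
        n_used += 1
    if n_used == 0:
        raise ValueError("no tree had out-of-bag samples; increase n or trees")
    return np.clip(drops / n_used, 0.0, None)


def oob_impurity_importance(forest, *_args, **_kw) -> np.ndarray:
    """Impurity-decrease importance as reported by the fitted forest."""
    return np.asarray(forest.feature_importances_)


@dataclass
class GridSearchResult:
    best_n_trees: int
    best_min_leaf: int
    cv_table: pd.DataFrame  # columns n_trees, min_leaf, fold scores, mean
    importances: pd.Series  # indexed by descriptor name
    best_cv_scores: list[float]
    forest: object  # best-cell forest refit on the full training split


def grid_search(X: pd.DataFrame, y: np.ndarray, task: Task,
                grid: HyperparameterGrid | None = None,
                folds: int = 3, seed: int = 0,
                importance: str = "oob_permutation") -> GridSearchResult:
    """Tune (n_trees, min_leaf) by k-fold CV and measure OOB importances.

    The best cell maximises the mean CV score (R^2 for regression,
    accuracy for classification); ties prefer fewer trees, then a larger
    minimum leaf.  The best forest is refit on all supplied rows and its
    out-of-bag variable importances are attached to the result.
    """
    if grid is None:
        grid = default_regression_grid() if task == "regression" else default_classification_grid()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    if task == "classification":
        _, counts = np.unique(yv, return_counts=True)
        if len(counts) < 2:
            raise ValueError("classification needs at least 2 classes")
        if counts.min() < folds:
            raise ValueError(
                f"rarest class has {counts.min()} samples < {folds} folds; "
                "a fold would see a single class")
        cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    else:
        cv = KFold(folds, shuffle=True, random_state=seed)

    rows = []
    best = None
    for n_trees, min_leaf in grid.cells():
        forest = _make_forest(task, n_trees, min_leaf, seed)
        scores = cross_val_score(forest, Xv, yv, cv=cv, n_jobs=1)
        rows.append({"n_trees": n_trees, "min_leaf": min_leaf,
                     **{f"fold{i}": s for i, s in enumerate(scores)},
                     "mean_score": float(scores.mean())})
        key = (float(scores.mean()), -n_trees, min_leaf)
        if best is None or key > best[0]:
            best = (key, n_trees, min_leaf, [float(s) for s in scores])
    _, bt, bm, bscores = best

    forest = _make_forest(task, bt, bm, seed, oob=True).fit(Xv, yv)
    if importance == "oob_permutation":
        imp = oob_permutation_importance(forest, Xv, yv, seed=seed)
    elif importance == "impurity":
        imp = oob_impurity_importance(forest)
    else:
        raise ValueError(f"unknown importance kind {importance!r}")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(Xv.shape[1]))
    return GridSearchResult(best_n_trees=bt, best_min_leaf=bm,
                            cv_table=pd.DataFrame(rows),
                            importances=pd.Series(imp, index=names),
                            best_cv_scores=bscores, forest=forest)


def select_by_relative_importance(importances: pd.Series | dict,
                                  threshold: float = 0.01) -> list[str]:
    """Variables whose importance exceeds ``threshold`` of the largest one.

    Each importance is divided by the maximum; names with a ratio
    strictly above the threshold (default 1%) are selected, preserving
    input order.
    """
    imp = pd.Series(importances, dtype=float)
    top = imp.max()
    if not top > 0:
        raise ValueError("all importances are zero; nothing to select")
    return [str(n) for n, v in imp.items() if v / top > threshold]


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to reuse it."""

    task: Task
    selected_variables: list[str]
    n_trees: int
    min_leaf: int
    seed: int
    ensemble: object
    importances: dict[str, float] = field(default_factory=dict)
    cv_scores: list[float] = field(default_factory=list)
    train_score: float | None = None
    oob_score: float | None = None
    schema_labels: tuple[str, ...] | None = None

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.selected_variables if c not in X.columns]
            if missing:
                raise KeyError(f"input table lacks selected variable(s): {missing}")
            return X.loc[:, self.selected_variables].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.selected_variables):
            raise ValueError(
                f"expected {len(self.selected_variables)} columns, got {X.shape[1]}")
        return X


def fit_final(X: pd.DataFrame, y: np.ndarray, selected: Sequence[str],
              n_trees: int, min_leaf: int, task: Task, seed: int = 0,
              cv_scores: Sequence[float] = ()) -> TrainedModel:
    """Refit a forest on the full data restricted to the selected variables."""
    selected = [str(s) for s in selected]
    if isinstance(X, pd.DataFrame):
        missing = [c for c in selected if c not in X.columns]
        if missing:
            raise KeyError(f"selected variable(s) missing from X: {missing}")
        Xs = X.loc[:, selected].to_numpy(dtype=float)
    else:
        Xs = np.asarray(X, dtype=float)
    yv = np.asarray(y)
    forest = _make_forest(task, n_trees, min_leaf, seed, oob=True).fit(Xs, yv)
    model = TrainedModel(task=task, selected_variables=selected,
                         n_trees=n_trees, min_leaf=min_leaf, seed=seed,
                         ensemble=forest, cv_scores=list(cv_scores),
                         train_score=float(forest.score(Xs, yv)))
    try:
        model.oob_score = float(forest.oob_score_)
    except AttributeError:  # pragma: no cover - tiny forests may lack OOB rows
        model.oob_score = None
    if task == "classification":
        model.schema_labels = tuple(str(c) for c in forest.classes_)
    return model


def predict_lc50(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted log10 LC50 (mg/L) for each row of X."""
    if model.task != "regression":
        raise ValueError("predict_lc50 requires a regression model")
    if model.ensemble is None:
        raise NotFittedError("model has no fitted ensemble")
    return np.asarray(model.ensemble.predict(model._matrix(X)), dtype=float)


def predict_category_direct(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Directly classified toxicity category for each row of X."""
    if model.task != "classification":
        raise ValueError("predict_category_direct requires a classification model")
    if model.ensemble is None:
        raise NotFittedError("model has no fitted ensemble")
    return np.asarray(model.ensemble.predict(model._matrix(X)))


def two_step_categorize(regressor: TrainedModel, schema: ToxicityCategorySchema,
                        X: pd.DataFrame,
                        masses: Sequence[float] | None = None) -> np.ndarray:
    """Regress log LC50, then threshold the prediction into a category.

    GHS schemas threshold 10^(predicted log LC50); k-means schemas need
    the monoisotopic masses and assign the nearest centroid to
    (predicted log LC50, mass).
    """
    preds = predict_lc50(regressor, X)
    if schema.provenance == "ghs":
        return np.asarray([assign_ghs(10.0 ** p) for p in preds])
    if masses is None:
        raise ValueError("k-means schema requires monoisotopic masses")
    masses = np.asarray(masses, dtype=float)
    if masses.shape[0] != preds.shape[0]:
        raise ValueError("masses length does not match number of rows")
    return np.asarray([assign_kmeans(schema.categorizer, (p, m))
                       for p, m in zip(preds, masses)])


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist a model (joblib binary + JSON sidecar with its settings)."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "format_version": 1,
        "task": model.task,
        "n_trees": model.n_trees,
        "min_leaf": model.min_leaf,
        "seed": model.seed,
        "selected_variables": model.selected_variables,
        "cv_scores": model.cv_scores,
        "train_score": model.train_score,
        "oob_score": model.oob_score,
        "schema_labels": list(model.schema_labels) if model.schema_labels else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model
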