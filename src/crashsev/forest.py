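"""Random-forest comparator for severity prediction.

A bagged ensemble of decision trees: each tree is grown on a bootstrap
resample of the data (same size, with replacement) and considers a random
subset of features — by default sqrt(p) per split, the standard rule; a
per-tree subsetting mode is available behind ``feature_mode``.  Prediction
is an equal-weight majority vote over trees, with ties broken toward the
less severe level.  Tree growing itself delegates to scikit-learn; the
voting, tie-breaking, tuning, and cross-validation contracts live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .datasets import covariate_columns
from .evaluation import ConfusionMatrix
from .severity import SEVERITY_LEVELS


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble settings.

    ``max_features_rule`` is ``"sqrt"`` (floor of sqrt(p)) or an explicit
    integer; ``feature_mode`` chooses whether the random feature subset is
    drawn per split (standard) or once per tree.

    ``min_samples_leaf`` defaults to 25: with purely binary covariates the
    design has far more cells than observations, and fully grown trees end
    in near-singleton leaves whose majority vote is dominated by sampling
    noise — on imbalanced data such a forest predicts *worse* than the
    majority class.  Leaves of a few dozen observations let each tree
    estimate the 3-class cell posterior instead.  Set it to 1 to recover
    fully grown trees.
    """

    n_trees: int = 652
    max_features_rule: str | int = "sqrt"
    seed: int = 0
    cv_folds: int = 10
    bootstrap: bool = True
    feature_mode: str = "per_split"
    max_depth: int | None = None
    min_samples_leaf: int = 25

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.feature_mode not in ("per_split", "per_tree"):
            raise ValueError("feature_mode must be 'per_split' or 'per_tree'")

    def max_features(self, p: int) -> int:
        if self.max_features_rule == "sqrt":
            return max(1, int(np.sqrt(p)))
        m = int(self.max_features_rule)
        if not 1 <= m <= p:
            raise ValueError(f"max_features {m} outside [1, {p}]")
        return m


def split_xy(data: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariate matrix and severity labels from an analysis table."""
    cols = covariate_columns(data)
    return data[cols], data["severity"].to_numpy(dtype=object)


class CrashForest:
    """A fitted ensemble with equal-weight mode voting.

    Use :func:`fit_forest` to construct.
    """

    def __init__(self, config: ForestConfig, feature_names: list[str], levels):
        self.config = config
        self.feature_names = list(feature_names)
        self.levels = tuple(levels)
        self._trees: list[tuple[DecisionTreeClassifier, np.ndarray]] = []

    @property
    def n_trees(self) -> int:
        return len(self._trees)

    def vote_counts(self, X: pd.DataFrame) -> np.ndarray:
        """(n, K) per-level vote counts; rows sum to the number of trees."""
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature(s) {missing} missing from data")
        Xa = X[self.feature_names].to_numpy()
        counts = np.zeros((len(X), len(self.levels)), dtype=np.int64)
        lut = {lvl: k for k, lvl in enumerate(self.levels)}
        for tree, feat_idx in self._trees:
            pred = tree.predict(Xa[:, feat_idx])
            idx = np.array([lut[p] for p in pred])
            counts[np.arange(len(X)), idx] += 1
        return counts

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Majority vote; ties resolve toward the less severe level."""
        counts = self.vote_counts(X)
        # levels are ordered least-severe first and argmax returns the
        # first maximum, which is exactly the tie rule
        return np.array(self.levels, dtype=object)[np.argmax(counts, axis=1)]


def fit_forest(
    data: pd.DataFrame, config: ForestConfig | None = None
) -> CrashForest:
    """Grow the ensemble on an analysis table (severity + 0/1 covariates)."""
    config = config or ForestConfig()
    X, y = split_xy(data)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 severity classes to fit a forest")
    levels = [lvl for lvl in SEVERITY_LEVELS if lvl in set(classes)]
    p = X.shape[1]
    forest = CrashForest(config, list(X.columns), SEVERITY_LEVELS)
    m = config.max_features(p)
    rng = np.random.default_rng(config.seed)
    Xa = X.to_numpy()

    if config.feature_mode == "per_split":
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=m,
            bootstrap=config.bootstrap,
            criterion="gini",
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=config.seed,
            n_jobs=1,
        )
        clf.fit(Xa, y)
        all_feat = np.arange(p)
        forest._trees = [(t, all_feat) for t in clf.estimators_]
        # sklearn trees predict class indices into clf.classes_; wrap so
        # CrashForest sees labels
        forest._trees = [
            (_LabelledTree(t, clf.classes_), all_feat) for t in clf.estimators_
        ]
    else:  # per-tree feature subsetting
        n = len(X)
        for _ in range(config.n_trees):
            feat_idx = np.sort(rng.choice(p, size=m, replace=False))
            rows = rng.integers(0, n, size=n) if config.bootstrap else np.arange(n)
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_depth=config.max_depth,
                min_samples_leaf=config.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xa[rows][:, feat_idx], y[rows])
            forest._trees.append((tree, feat_idx))
    return forest


class _LabelledTree:
    """Adapter: a tree inside a sklearn forest predicts class indices."""

    def __init__(self, tree, classes):
        self._tree = tree
        self._classes = np.asarray(classes)

    def predict(self, X):
        out = self._tree.predict(X)
        if out.dtype.kind in "if":  # indices into the parent's classes_
            return self._classes[out.astype(np.int64)]
        return out


def predict_forest(forest: CrashForest, data: pd.DataFrame) -> np.ndarray:
    """Predict severities for an analysis table (or bare covariate table)."""
    cols = [c for c in data.columns if c in forest.feature_names]
    return forest.predict(data[cols])


def kfold_cv(
    data: pd.DataFrame,
    config: ForestConfig | None = None,
    fitter=fit_forest,
) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    Every row is predicted exactly once by a model that never saw it; the
    pooled predictions give one confusion matrix.  A class with fewer
    members than folds degrades stratification (scikit-learn warns; we
    surface that warning once).
    """
    config = config or ForestConfig()
    n = len(data)
    if n < config.cv_folds:
        raise ValueError("need at least as many rows as folds")
    y = data["severity"].to_numpy(dtype=object)
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    predicted = np.empty(n, dtype=object)
    fold_of = np.empty(n, dtype=np.int64)
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "once", message=".*least populated class.*"
        )
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            model = fitter(data.iloc[train_idx], config)
            predicted[test_idx] = predict_forest(model, data.iloc[test_idx])
            fold_of[test_idx] = fold
    preds = pd.DataFrame(
        {
            "crash_id": data["crash_id"].to_numpy()
            if "crash_id" in data.columns
            else np.arange(n),
            "fold": fold_of,
            "actual": y,
            "predicted": predicted,
        }
    )
    return preds, ConfusionMatrix.from_labels(y, predicted)


def tune_n_trees(
    data: pd.DataFrame,
    grid: list[int],
    config: ForestConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Learning curve over candidate tree counts; select the argmax.

    Returns ``(curve, selected)`` where ``curve`` has columns
    ``n_trees, cv_accuracy``.  Ties select the smallest count.
    """
    config = config or ForestConfig()
    if not grid:
        raise ValueError("grid must be nonempty")
    if any(g < 1 for g in grid):
        raise ValueError("tree counts must be >= 1")
    rows = []
    for n_trees in sorted(grid):
        cfg = ForestConfig(
            n_trees=n_trees,
            max_features_rule=config.max_features_rule,
            seed=config.seed,
            cv_folds=config.cv_folds,
            bootstrap=config.bootstrap,
            feature_mode=config.feature_mode,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
        )
        _, cm = kfold_cv(data, cfg)
        rows.append({"n_trees": n_trees, "cv_accuracy": cm.overall_accuracy()})
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["cv_accuracy"].idxmax(), "n_trees"]
    return curve, int(best)
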