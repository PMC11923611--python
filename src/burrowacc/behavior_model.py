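"""Supervised behaviour classification and the 14 -> 4 category map.

The ethogram has 14 behaviours regularly seen in tunnel-system
observations; analyses run on four coarse categories: rest, excavating
activities (digging, sweeping soil, back-kicking for soil tightening),
movement (running, walking, food carrying) and other.  A gradient-boosted
tree classifier maps 50-feature window vectors to behaviours; evaluation
uses leave-individuals-out grouped cross-validation so that windows of
one animal never straddle the train/test split.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import GroupKFold

__all__ = [
    "BEHAVIOURS",
    "CATEGORIES",
    "CATEGORY_MAP",
    "map_to_categories",
    "ClassifierModel",
    "EvaluationReport",
    "train_classifier",
    "predict",
    "evaluate_grouped_cv",
]

BEHAVIOURS: tuple[str, ...] = (
    "rest",
    "dig", "sweep", "back-kick",
    "run", "walk", "food-carry",
    "eat", "groom", "scratch", "sniff", "gnaw", "rear", "shuffle",
)

CATEGORIES: tuple[str, ...] = ("rest", "excavate", "move", "other")

CATEGORY_MAP: dict[str, str] = {
    "rest": "rest",
    "dig": "excavate", "sweep": "excavate", "back-kick": "excavate",
    "run": "move", "walk": "move", "food-carry": "move",
    "eat": "other", "groom": "other", "scratch": "other",
    "sniff": "other", "gnaw": "other", "rear": "other", "shuffle": "other",
}

DEFAULT_PARAMS: dict = {"n_trees": 300, "max_depth": 3, "learning_rate": 0.1}


def map_to_categories(behaviour: str) -> str:
    """Map a behaviour to its analysis category (total on the vocabulary)."""
    try:
        return CATEGORY_MAP[behaviour]
    except KeyError:
        raise ValueError(f"unknown behaviour {behaviour!r}") from None


@dataclass
class ClassifierModel:
    """A trained behaviour classifier plus its training metadata."""

    estimator: HistGradientBoostingClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    params: dict

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClassifierModel):
            raise ValueError("not a burrowacc classifier archive")
        return model


@dataclass
class EvaluationReport:
    """Aggregated out-of-fold evaluation of a grouped CV run."""

    behaviours: tuple[str, ...]
    confusion_behaviour: np.ndarray      # rows: truth, cols: predicted
    confusion_category: np.ndarray
    category_accuracy: float
    per_behaviour_accuracy: dict[str, float]
    fold_of_group: dict[str, int]

    def __post_init__(self) -> None:
        assert self.confusion_behaviour.sum() == self.confusion_category.sum()


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("NaN/inf in feature matrix")
    return X


def train_classifier(
    X: np.ndarray,
    labels,
    params: dict | None = None,
    seed: int = 0,
    feature_names=None,
) -> ClassifierModel:
    """Fit the boosted-tree behaviour classifier.

    Defaults: 300 trees of depth 3, learning rate 0.1.  Deterministic
    for a given seed; refuses single-class input.
    """
    X = _check_features(X)
    y = np.asarray(labels)
    unknown = set(y) - set(BEHAVIOURS)
    if unknown:
        raise ValueError(f"labels outside the vocabulary: {sorted(unknown)}")
    if len(set(y)) < 2:
        raise ValueError("need at least 2 behaviour classes to train")
    p = dict(DEFAULT_PARAMS, **(params or {}))
    est = HistGradientBoostingClassifier(
        max_iter=p["n_trees"],
        max_depth=p["max_depth"],
        learning_rate=p["learning_rate"],
        random_state=seed,
        early_stopping=False,
    )
    est.fit(X, y)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    return ClassifierModel(est, names, tuple(est.classes_), seed, p)


def predict(model: ClassifierModel, X: np.ndarray):
    """Predict behaviours and categories; X is (n, n_features) or (n_features,)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    X = _check_features(X)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature length {X.shape[1]} != model's {len(model.feature_names)}"
        )
    beh = model.estimator.predict(X)
    cat = np.array([CATEGORY_MAP[b] for b in beh])
    if single:
        return beh[0], cat[0]
    return beh, cat


def _confusion(y_true, y_pred, labels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m


def evaluate_grouped_cv(
    X: np.ndarray,
    labels,
    group_ids,
    n_folds: int = 4,
    seed: int = 0,
    params: dict | None = None,
) -> EvaluationReport:
    """Leave-individuals-out cross-validation of the classifier.

    Individuals (``group_ids``) are partitioned into ``n_folds`` folds;
    each fold is predicted by a model trained on the others, and the
    report aggregates the out-of-fold predictions.
    """
    X = _check_features(X)
    y = np.asarray(labels)
    g = np.asarray(group_ids)
    uniq = np.unique(g)
    if len(uniq) < n_folds:
        raise ValueError(f"{len(uniq)} individuals < {n_folds} folds")
    # shuffle individuals reproducibly before the contiguous GroupKFold split
    rng = np.random.default_rng(seed)
    order = {ind: r for ind, r in zip(uniq, rng.permutation(len(uniq)))}
    sort_key = np.array([order[i] for i in g])
    pred = np.empty(len(y), dtype=y.dtype)
    fold_of_group: dict[str, int] = {}
    gkf = GroupKFold(n_splits=n_folds)
    for fold, (tr, te) in enumerate(gkf.split(X, y, groups=sort_key)):
        model = train_classifier(X[tr], y[tr], params=params, seed=seed)
        pred[te] = model.estimator.predict(X[te])
        for ind in np.unique(g[te]):
            fold_of_group[str(ind)] = fold
    behaviours = tuple(sorted(set(y) | set(pred)))
    cb = _confusion(y, pred, behaviours)
    cat_true = [CATEGORY_MAP[b] for b in y]
    cat_pred = [CATEGORY_MAP[b] for b in pred]
    cc = _confusion(cat_true, cat_pred, CATEGORIES)
    cat_acc = float(np.trace(cc) / cc.sum())
    per_beh = {}
    for i, b in enumerate(behaviours):
        support = cb[i].sum()
        per_beh[b] = float(cb[i, i] / support) if support else float("nan")
    return EvaluationReport(behaviours, cb, cc, cat_acc, per_beh, fold_of_group)
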