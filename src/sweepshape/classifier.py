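"""Extra-Trees classification of the five sweep classes.

The core estimator is :class:`SweepShapeClassifier`, a scikit-learn
compatible wrapper around an extremely-randomized-trees ensemble of 100
trees whose hyperparameters are chosen by cross-validated grid search.  It
consumes the 99-dimensional shape feature vectors and predicts one of
{hard, hard-linked, soft, soft-linked, neutral} with posterior class
probabilities given by the ensemble vote fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from .features import FEATURE_NAMES, FEATURE_ORDER_VERSION
from .simulate import SWEEP_CLASSES, SweepScenario

__all__ = [
    "CLASS_ORDER",
    "LabeledSet",
    "SweepShapeClassifier",
    "hyperparameter_grid",
    "assemble_training_set",
    "concat_labeled_sets",
    "feature_importances",
    "save_model",
    "load_model",
]

CLASS_ORDER = SWEEP_CLASSES


def hyperparameter_grid(kind: str = "full", n_features: int = 99) -> dict:
    """Hyperparameter grids for the cross-validated search.

    ``full`` covers max_features in {1, 3, sqrt(F), F}, max_depth in
    {3, 10, unlimited}, min_samples_split in {2, 3, 10} (2 being the
    smallest legal split), min_samples_leaf in {1, 3, 10}, bootstrap on/off
    and Gini versus information-gain split criteria (432 combinations).
    ``small`` is a 2-point grid over the parameter that matters most in
    practice (how many features each split may consider), for desk-scale
    runs.
    """
    if isinstance(kind, dict):
        return kind
    if kind == "full":
        return {
            "max_features": [1, 3, "sqrt", None],
            "max_depth": [3, 10, None],
            "min_samples_split": [2, 3, 10],
            "min_samples_leaf": [1, 3, 10],
            "bootstrap": [True, False],
            "criterion": ["gini", "entropy"],
        }
    if kind == "small":
        return {
            "max_features": ["sqrt", None],
            "max_depth": [None],
        }
    raise ValueError("grid must be 'full', 'small' or an explicit parameter grid")


class SweepShapeClassifier(ClassifierMixin, BaseEstimator):
    """Extra-Trees sweep classifier with cross-validated hyperparameters.

    Parameters
    ----------
    n_estimators : int
        Number of trees in the ensemble (100 throughout).
    grid : {'full', 'small'} or dict
        Hyperparameter grid searched with ``folds``-fold stratified CV,
        scored by mean accuracy (classes are balanced by construction).
    folds : int
        Cross-validation folds (10 by default).
    random_state : int or None
        Master seed for the grid search folds, tree construction and any
        bootstrap resampling.

    Attributes
    ----------
    estimator_ : ExtraTreesClassifier
        The winning ensemble, refit on all training data.
    best_params_ : dict
        Chosen hyperparameters.
    cv_score_ : float
        Mean cross-validated accuracy of the winning combination.
    classes_ : ndarray
        Class labels in the estimator's order.
    feature_importances_ : ndarray
        Normalized mean decrease in Gini impurity (sums to 1).
    feature_order_version_ : str
        Version tag of the feature ordering this model expects.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        grid: str | dict = "full",
        folds: int = 10,
        random_state: int | None = None,
        n_jobs: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.grid = grid
        self.folds = folds
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain at least two classes")
        param_grid = hyperparameter_grid(self.grid, X.shape[1])
        base = ExtraTreesClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        cv = StratifiedKFold(
            n_splits=self.folds, shuffle=True, random_state=self.random_state
        )
        search = GridSearchCV(
            base, param_grid, scoring="accuracy", cv=cv, n_jobs=self.n_jobs, refit=True
        )
        search.fit(X, y)
        self.estimator_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_score_ = float(search.best_score_)
        self.cv_results_ = search.cv_results_
        self.classes_ = self.estimator_.classes_
        self.n_features_in_ = X.shape[1]
        imp = self.estimator_.feature_importances_
        self.feature_importances_ = imp / imp.sum() if imp.sum() > 0 else imp
        self.feature_order_version_ = (
            FEATURE_ORDER_VERSION
            if X.shape[1] == len(FEATURE_NAMES)
            else f"custom-{X.shape[1]}"
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(np.asarray(X, dtype=float))


@dataclass
class LabeledSet:
    """Feature vectors with class labels, ready for ``fit``."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def concat_labeled_sets(sets: list[LabeledSet]) -> LabeledSet:
    """Concatenate per-class sets from several alpha-range batches."""
    return LabeledSet(
        np.concatenate([s.X for s in sets]), np.concatenate([s.y for s in sets])
    )


def assemble_training_set(
    sim_outputs: list[tuple[SweepScenario, np.ndarray]],
    R: int = 1000,
    rng: np.random.Generator | int | None = None,
    strict: bool = True,
) -> LabeledSet:
    """Assemble the balanced five-class training set.

    ``sim_outputs`` pairs each simulated scenario with its feature vector.
    Centrally swept simulations form the hard/soft classes; the linked
    classes are R draws from the pool of simulations whose sweep lies in a
    non-central subwindow (a sweep even one subwindow off-centre is linked,
    not a sweep, by definition); neutral simulations form the fifth class.

    With ``strict`` the hard and soft pools must cover all 11 sweep
    positions (the full training design); an incomplete design raises.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pools: dict[str, list[np.ndarray]] = {c: [] for c in CLASS_ORDER}
    positions: dict[str, set[int]] = {"hard": set(), "soft": set()}
    for scenario, fv in sim_outputs:
        pools[scenario.true_class].append(np.asarray(fv))
        if scenario.is_sweep:
            positions[scenario.true_class.split("-")[0]].add(scenario.sweep_subwindow)
    if strict:
        n_sub = 11
        for kind, seen in positions.items():
            if seen and seen != set(range(n_sub)):
                raise ValueError(
                    f"{kind}-sweep simulations cover positions {sorted(seen)}, "
                    f"not all {n_sub} subwindows; pass strict=False for partial designs"
                )
    X_parts, y_parts = [], []
    for cls in CLASS_ORDER:
        pool = pools[cls]
        if len(pool) < R:
            raise ValueError(f"class {cls!r} has only {len(pool)} simulations, need {R}")
        take = rng.choice(len(pool), size=R, replace=False)
        X_parts.append(np.stack([pool[i] for i in take]))
        y_parts.append(np.full(R, cls, dtype=object))
    return LabeledSet(np.concatenate(X_parts), np.concatenate(y_parts))


def feature_importances(model: SweepShapeClassifier) -> list[tuple[str, float]]:
    """(feature name, relative Gini importance), descending; sums to 1."""
    check_is_fitted(model, "estimator_")
    names = FEATURE_NAMES
    if model.n_features_in_ != len(names):
        names = tuple(f"f{i}" for i in range(model.n_features_in_))
    order = np.argsort(model.feature_importances_)[::-1]
    return [(names[i], float(model.feature_importances_[i])) for i in order]


_MODEL_FORMAT = 1


def save_model(model: SweepShapeClassifier, path) -> None:
    """Serialize a fitted classifier with its feature-order version tag."""
    check_is_fitted(model, "estimator_")
    payload = {
        "format": _MODEL_FORMAT,
        "model": model,
        "class_order": list(model.classes_),
        "feature_names": list(FEATURE_NAMES)
        if model.n_features_in_ == len(FEATURE_NAMES)
        else None,
        "feature_order_version": model.feature_order_version_,
        "best_params": model.best_params_,
        "importances": model.feature_importances_.tolist(),
    }
    joblib.dump(payload, path)


def load_model(path) -> SweepShapeClassifier:
    payload = joblib.load(path)
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError("unrecognized model file format")
    return payload["model"]
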