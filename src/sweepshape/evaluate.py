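"""Evaluation of trained sweep classifiers.

Provides per-instance predictions with posteriors, binary confidence scores
for composite tasks (e.g. sweep-vs-unselected), the balanced composite test
sets used for benchmarking, ROC/AUC computation, and the
distance-from-sweep classification profile (the heatmap view of how calls
change as the true sweep moves away from the classified window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .classifier import CLASS_ORDER, SweepShapeClassifier
from .features import FEATURE_ORDER_VERSION

__all__ = [
    "Prediction",
    "RocResult",
    "predict_one",
    "binary_score",
    "build_composite_test_set",
    "roc_auc",
    "distance_profile",
    "COMPOSITE_TASKS",
]


@dataclass(frozen=True)
class Prediction:
    label: str
    posteriors: dict[str, float]


def predict_one(model: SweepShapeClassifier, fv: np.ndarray) -> Prediction:
    """Classify a single feature vector, checking the feature-order tag."""
    fv = np.asarray(fv, dtype=float)
    expected = (
        FEATURE_ORDER_VERSION if fv.size == model.n_features_in_ == 99 else None
    )
    if fv.size != model.n_features_in_ or (
        expected is not None and model.feature_order_version_ != expected
    ):
        raise ValueError(
            f"feature vector ({fv.size} values) does not match the model's "
            f"feature order {model.feature_order_version_!r}"
        )
    proba = model.predict_proba(fv.reshape(1, -1))[0]
    posteriors = dict(zip(model.classes_.tolist(), proba.tolist()))
    label = model.classes_[int(np.argmax(proba))]
    return Prediction(label=label, posteriors=posteriors)


def binary_score(pred: Prediction, positive_classes) -> float:
    """Summed posterior probability of the positive composite classes."""
    positive = list(positive_classes)
    if not positive:
        raise ValueError("positive_classes must be nonempty")
    unknown = [c for c in positive if c not in pred.posteriors]
    if unknown:
        raise ValueError(f"unknown class name(s): {unknown}")
    return float(sum(pred.posteriors[c] for c in positive))


def _scores(model, X, positive_classes) -> np.ndarray:
    unknown = [c for c in positive_classes if c not in model.classes_]
    if unknown:
        raise ValueError(f"unknown class name(s): {unknown}")
    proba = model.predict_proba(X)
    cols = [int(np.flatnonzero(model.classes_ == c)[0]) for c in positive_classes]
    return proba[:, cols].sum(axis=1)


#: composite binary tasks: (positive subclasses, negative subclasses)
COMPOSITE_TASKS = {
    "hard_vs_neutral": (("hard",), ("neutral",)),
    "soft_vs_neutral": (("soft",), ("neutral",)),
    "sweep_vs_neutral": (("hard", "soft"), ("neutral",)),
    "hard_vs_soft": (("hard",), ("soft",)),
    "sweep_vs_unselected": (("hard", "soft"), ("neutral", "hard-linked", "soft-linked")),
}


def build_composite_test_set(
    task: str,
    per_class_pools: dict[str, np.ndarray],
    scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Balanced binary test set with equal parts of each subclass.

    Each side totals ``round(1000 * scale)`` instances.  Composite sides are
    split evenly across their subclasses; any remainder is filled with
    instances drawn from randomly chosen subclasses of that side (so the
    full-scale unselected side is 333 + 333 + 333 + 1).  Returns
    ``(X, labels, positive_classes)`` with labels 1 for the positive side.
    """
    if task not in COMPOSITE_TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(COMPOSITE_TASKS)}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos_classes, neg_classes = COMPOSITE_TASKS[task]
    n_side = int(round(1000 * scale))
    X_parts, y_parts = [], []
    for classes, label in ((pos_classes, 1), (neg_classes, 0)):
        counts = np.full(len(classes), n_side // len(classes))
        for k in rng.choice(len(classes), size=n_side - counts.sum(), replace=False):
            counts[k] += 1
        for cls, cnt in zip(classes, counts):
            pool = np.asarray(per_class_pools[cls])
            if len(pool) < cnt:
                raise ValueError(
                    f"pool for class {cls!r} has {len(pool)} instances, need {cnt}"
                )
            take = rng.choice(len(pool), size=cnt, replace=False)
            X_parts.append(pool[take])
            y_parts.append(np.full(cnt, label))
    return np.concatenate(X_parts), np.concatenate(y_parts), pos_classes


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, with ties counted half (the Mann–Whitney formulation; forest
    posteriors are quantized at 1/n_trees so ties are common).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def classifier_roc(
    model: SweepShapeClassifier,
    X: np.ndarray,
    labels: np.ndarray,
    positive_classes,
) -> RocResult:
    """ROC for a composite task scored by summed positive-class posteriors."""
    return roc_auc(_scores(model, X, tuple(positive_classes)), labels)


def distance_profile(
    model: SweepShapeClassifier,
    fvecs_by_offset: dict[int | str, np.ndarray],
) -> pd.DataFrame:
    """Fractions of predicted classes at each sweep offset.

    ``fvecs_by_offset`` maps a sweep offset in subwindows (negative = left of
    the classified centre, 0 = centred, or the string ``"neutral"``) to an
    array of feature vectors.  Returns a DataFrame whose rows (offsets) each
    sum to 1 across the five predicted classes.
    """
    rows = {}
    for offset, X in fvecs_by_offset.items():
        pred = model.predict(np.asarray(X))
        rows[offset] = {
            cls: float(np.mean(pred == cls)) for cls in CLASS_ORDER
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CLASS_ORDER))
    return df
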