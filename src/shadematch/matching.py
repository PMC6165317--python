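"""Shade selection: nearest-dE matching and supervised classifiers.

Two routes to a shade decision:

* **Euclidean** — compare the measured CIELAB color with each tab's
  representative (mean) color and pick the smallest dE.  This implicitly
  assumes spherical per-tab color distributions.
* **Classifier** — train a multiclass model on the raw per-measurement Lab
  triples.  The primary model is an SVM with a Gaussian RBF kernel
  (one-vs-one), whose boundaries can follow elongated, tilted clusters that
  defeat the nearest-mean rule; logistic regression, random forest and
  k-nearest neighbors are available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .colorspace import LabColor, delta_e
from .errors import MatchingError, StateError, ValidationError
from .shade_db import ShadeDatabase, label_order

__all__ = [
    "ALGORITHMS",
    "ClassifierModel",
    "MatchResult",
    "match_euclidean",
    "train_classifier",
    "match_classifier",
]

ALGORITHMS = ("svm", "lr", "rf", "knn")

#: Default RBF grid searched with internal 5-fold CV when no params given.
SVM_GRID = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.01, 0.1, 1.0, 10.0]}


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one shade decision."""

    predicted: str
    method: str
    score: float
    runner_up: Optional[str] = None


@dataclass
class ClassifierModel:
    """A fitted multiclass shade classifier over (L*, a*, b*) features."""

    algorithm: str
    estimator: object
    classes: tuple[str, ...]
    seed: int = 0

    def _check_fitted(self) -> None:
        if self.estimator is None or not hasattr(self.estimator, "classes_"):
            # GridSearchCV exposes classes_ only after fit
            try:
                getattr(self.estimator, "best_estimator_")
            except Exception:
                raise StateError("classifier has not been fitted") from None


def _check_color(color: LabColor) -> np.ndarray:
    v = color.to_array()
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"non-finite Lab component in {color}")
    return v


def match_euclidean(color: LabColor, db: ShadeDatabase) -> MatchResult:
    """Pick the tab whose representative color is nearest in dE.

    Ties (exactly equal distances) are broken by canonical 1M1 -> 5M3 label
    order; the runner-up is the second-nearest tab.
    """
    _check_color(color)
    if not db.representatives:
        raise MatchingError("database has no representative colors")
    items = sorted(db.representatives.items(), key=lambda kv: label_order(kv[0]))
    dists = [(delta_e(color, rep).delta_e, tab) for tab, rep in items]
    best_d, best_tab = min(dists, key=lambda t: t[0])
    runner = None
    rest = [(d, t) for d, t in dists if t != best_tab]
    if rest:
        runner = min(rest, key=lambda t: t[0])[1]
    return MatchResult(predicted=best_tab, method="euclidean", score=float(best_d), runner_up=runner)


def _build_estimator(algorithm: str, params: Optional[dict], seed: int, standardize: bool):
    params = dict(params or {})
    if algorithm == "svm":
        if params:
            est = SVC(kernel="rbf", decision_function_shape="ovo", random_state=seed, **params)
        else:
            est = GridSearchCV(
                SVC(kernel="rbf", decision_function_shape="ovo", random_state=seed),
                SVM_GRID,
                cv=5,
                n_jobs=1,
            )
    elif algorithm == "lr":
        est = LogisticRegression(max_iter=2000, random_state=seed, **params)
    elif algorithm == "rf":
        params.setdefault("n_estimators", 100)
        est = RandomForestClassifier(random_state=seed, **params)
    elif algorithm == "knn":
        params.setdefault("n_neighbors", 5)
        est = KNeighborsClassifier(**params)
    else:
        raise ValidationError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if standardize:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def train_classifier(
    db: ShadeDatabase,
    algorithm: str = "svm",
    params: Optional[dict] = None,
    seed: int = 0,
    *,
    standardize: bool = False,
) -> ClassifierModel:
    """Fit a multiclass shade classifier on the database measurements.

    Features are the CIELAB triples of the individual measurements; classes
    are the tab labels present.  For the SVM, explicit ``params`` (e.g.
    ``{"C": 10, "gamma": 0.1}``) bypass the default grid search.  Lab axes
    are commensurate, so no feature scaling is applied unless requested.
    """
    X, y = db.features()
    if X.shape[0] == 0:
        raise MatchingError("no training measurements")
    if not np.all(np.isfinite(X)):
        raise ValidationError("training features contain non-finite values")
    if len(set(y)) < 2:
        raise MatchingError("need at least 2 distinct classes to train")
    est = _build_estimator(algorithm, params, seed, standardize)
    est.fit(X, y)
    classes = tuple(sorted(set(y), key=label_order))
    return ClassifierModel(algorithm=algorithm, estimator=est, classes=classes, seed=seed)


def match_classifier(color: LabColor, model: ClassifierModel) -> MatchResult:
    """Predict the shade of a color with a fitted classifier.

    The score is the winning class's aggregated decision value (SVM) or
    probability (LR/RF/KNN); the runner-up is the second-ranked class.
    """
    v = _check_color(color).reshape(1, -1)
    model._check_fitted()
    est = model.estimator
    try:
        predicted = str(est.predict(v)[0])
    except Exception as exc:
        if not hasattr(est, "classes_") and not hasattr(est, "best_estimator_"):
            raise StateError("classifier has not been fitted") from exc
        raise

    score = math.nan
    runner = None
    ranked = _class_scores(est, v)
    if ranked is not None:
        order = sorted(ranked.items(), key=lambda kv: -kv[1])
        score = float(ranked[predicted])
        for label, _ in order:
            if label != predicted:
                runner = label
                break
    return MatchResult(predicted=predicted, method=model.algorithm, score=score, runner_up=runner)


def _class_scores(est, v: np.ndarray) -> Optional[dict[str, float]]:
    """Per-class ranking scores: probabilities if available, else OvO votes."""
    if hasattr(est, "predict_proba"):
        try:
            proba = est.predict_proba(v)[0]
            return dict(zip((str(c) for c in est.classes_), proba))
        except Exception:
            pass
    if hasattr(est, "decision_function"):
        classes = [str(c) for c in est.classes_]
        dec = np.ravel(est.decision_function(v))
        if len(classes) == 2:
            return {classes[0]: float(-dec[0]), classes[1]: float(dec[0])}
        # one-vs-one: accumulate signed margins into per-class totals
        scores = dict.fromkeys(classes, 0.0)
        k = 0
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                scores[classes[i]] += float(dec[k])
                scores[classes[j]] -= float(dec[k])
                k += 1
        return scores
    return None
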