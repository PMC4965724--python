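"""Instance-level reference classifiers (the comparative first approach).

Each 100 ms MAV instance is classified in isolation, without any temporal
context, by a standard classifier under stratified 10-fold cross-validation.
Channels are z-scored inside each fold with the training fold's statistics.
Reported: overall accuracy, per-class true-positive rate (recall) and the
confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .protocol import CLASS_CODES

__all__ = ["BaselineSpec", "BaselineResult", "run_baseline"]

_METHODS = ("decision-tree", "1-nn", "random-forest", "svm")


@dataclass(frozen=True)
class BaselineSpec:
    """A named instance-level classifier with its hyper-parameters.

    Defaults follow the comparative protocol: 25 trees for the random
    forest, K=1 with normalised Euclidean distance for the nearest
    neighbour, C=5 for the SVM (RBF kernel).
    """

    method: str = "random-forest"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")

    def build(self, seed: Optional[int] = None):
        p = dict(self.params)
        if self.method == "decision-tree":
            return DecisionTreeClassifier(random_state=seed, **p)
        if self.method == "1-nn":
            return KNeighborsClassifier(n_neighbors=p.pop("k", 1), **p)
        if self.method == "random-forest":
            return RandomForestClassifier(
                n_estimators=p.pop("n_trees", 25), random_state=seed, **p
            )
        return SVC(C=p.pop("C", 5.0), kernel=p.pop("kernel", "rbf"), random_state=seed, **p)


@dataclass
class BaselineResult:
    accuracy: float  # percent
    tpr: dict  # class -> percent recall
    confusion: pd.DataFrame  # rows = truth, columns = prediction


def run_baseline(
    values: np.ndarray,
    labels: Sequence[str],
    spec: BaselineSpec = BaselineSpec(),
    folds: int = 10,
    seed: Optional[int] = 0,
    classes: Sequence[str] = CLASS_CODES,
) -> BaselineResult:
    """Stratified k-fold CV of an instance-level classifier.

    ``values`` are raw (unnormalised) MAV instances; z-scoring happens inside
    each fold using only that fold's training statistics.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    present, counts = np.unique(labels, return_counts=True)
    too_few = [f"{c} ({n})" for c, n in zip(present, counts) if n < folds]
    if too_few:
        raise ValueError(
            f"classes with fewer instances than folds={folds}: {', '.join(too_few)}"
        )
    pipe = Pipeline([("scale", StandardScaler()), ("clf", spec.build(seed))])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = cross_val_predict(pipe, values, labels, cv=cv)

    classes = [c for c in classes if c in present] + sorted(set(present) - set(classes))
    cm = confusion_matrix(labels, preds, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    row_sums = cm.sum(axis=1)
    tpr = {
        c: (100.0 * cm[i, i] / row_sums[i] if row_sums[i] else float("nan"))
        for i, c in enumerate(classes)
    }
    return BaselineResult(accuracy=float(accuracy), tpr=tpr, confusion=confusion)
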