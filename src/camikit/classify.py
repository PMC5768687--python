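"""Phenotype classification, model selection and candidate ranking.

A small set of user annotations (nucleus -> phenotype class) trains
several candidate classifiers on the 92-feature profiles; stratified
k-fold cross-validation (default k = 10) picks the best-performing
model, which is then refit on every annotation and used to predict
the class of every cell with a confidence score. Candidates are
ranked per class by confidence and the top of the ranking (default
quota 200 per class) becomes the isolation list.

A reserved "discard" class can be trained (artifacts, debris) but is
never selectable, and cells carrying exclusion flags (border-touching,
user-removed) are never selected either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "DISCARD_CLASS",
    "TrainingSet",
    "ModelReport",
    "PhenotypePrediction",
    "SelectionList",
    "default_algorithms",
    "train_and_select",
    "predict_all",
    "rank_and_pick",
]

DISCARD_CLASS = "discard"
_TIE_TOL = 1e-9


@dataclass
class TrainingSet:
    """Annotated feature matrix: n cells x 92 features plus labels."""

    features: np.ndarray
    labels: np.ndarray
    label_set: tuple[str, ...]
    provenance: pd.DataFrame | None = None  # slide id, nucleus label per row

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("training features contain non-finite values")
        unknown = set(self.labels) - set(self.label_set)
        if unknown:
            raise ValueError(f"labels outside the declared set: {sorted(unknown)}")
        if len(set(self.labels)) < 2:
            raise ValueError("need at least 2 classes to train")


@dataclass
class ModelReport:
    cv_accuracy: dict[str, float]
    chosen_algorithm: str
    k: int
    seed: int

    def __post_init__(self) -> None:
        for name, acc in self.cv_accuracy.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy for {name} outside [0, 1]")
        best = max(self.cv_accuracy.values())
        if self.cv_accuracy[self.chosen_algorithm] < best - 1e-12:
            raise ValueError("chosen algorithm is not the CV maximum")


@dataclass
class PhenotypePrediction:
    slide_id: str
    nucleus_label: int
    predicted_class: str
    confidence: float
    scores: dict[str, float]
    ambiguous: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        total = sum(self.scores.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"score vector sums to {total}, expected 1")


@dataclass
class SelectionList:
    cells: pd.DataFrame  # columns: slide_id, nucleus_label, class, confidence
    shortfalls: dict[str, int] = field(default_factory=dict)


def default_algorithms(seed: int) -> dict[str, object]:
    """Candidate classifiers evaluated by cross-validation."""
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1
        ),
        "logistic_regression": Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=5000, random_state=seed)),
        ]),
        "knn": Pipeline([
            ("scale", StandardScaler()),
            ("clf", KNeighborsClassifier(n_neighbors=5)),
        ]),
        "svm": Pipeline([
            ("scale", StandardScaler()),
            ("clf", CalibratedClassifierCV(SVC(random_state=seed),
                                           ensemble=False)),
        ]),
    }


def train_and_select(
    train: TrainingSet,
    algorithms: dict[str, object] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[object, ModelReport]:
    """Pick the best classifier by stratified k-fold CV, refit on all data.

    Ties in CV accuracy are broken by algorithm order in the candidate
    dict (insertion order), so the report is deterministic for a fixed
    seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(train.labels)
    if n < k:
        raise ValueError(f"n = {n} annotations but k = {k} folds")
    counts = pd.Series(train.labels).value_counts()
    thin = counts[counts < k]
    if not thin.empty:
        raise ValueError(
            f"class(es) {list(thin.index)} have fewer than k = {k} members; "
            "reduce k or annotate more cells"
        )
    if algorithms is None:
        algorithms = default_algorithms(seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies: dict[str, float] = {}
    for name, est in algorithms.items():
        scores = cross_val_score(est, train.features, train.labels, cv=cv,
                                 scoring="accuracy", n_jobs=1)
        accuracies[name] = float(scores.mean())
    chosen = max(accuracies, key=lambda name: accuracies[name])
    model = algorithms[chosen]
    model.fit(train.features, train.labels)
    report = ModelReport(cv_accuracy=accuracies, chosen_algorithm=chosen,
                         k=k, seed=seed)
    return model, report


def predict_all(
    model: object,
    features: np.ndarray,
    nucleus_labels: list[int],
    slide_id: str = "slide",
    exclusions: dict[int, str] | None = None,
) -> list[PhenotypePrediction]:
    """One prediction per cell; confidence is the winning class score.

    Exact score ties are broken by class-name order and flagged
    ambiguous. ``exclusions`` maps nucleus label -> reason for cells
    that must never be selected (border-touching etc.).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] != len(nucleus_labels):
        raise ValueError("feature matrix and labels disagree")
    n_expected = getattr(model, "n_features_in_", features.shape[1])
    if features.shape[1] != n_expected:
        raise ValueError(
            f"feature dimension {features.shape[1]} != training {n_expected}"
        )
    exclusions = exclusions or {}
    proba = model.predict_proba(features)
    classes = [str(c) for c in model.classes_]  # sklearn sorts lexically
    order = np.argsort(classes)
    preds: list[PhenotypePrediction] = []
    for row, nucleus in zip(proba, nucleus_labels):
        best = None
        for idx in order:  # class-name order -> deterministic tie-break
            if best is None or row[idx] > row[best] + _TIE_TOL:
                best = idx
        ambiguous = sum(1 for idx in order if row[idx] >= row[best] - _TIE_TOL) > 1
        total = float(row.sum())
        scores = {c: float(v) / total for c, v in zip(classes, row)}
        reason = exclusions.get(nucleus, "")
        preds.append(PhenotypePrediction(
            slide_id=slide_id,
            nucleus_label=int(nucleus),
            predicted_class=classes[best],
            confidence=scores[classes[best]],
            scores=scores,
            ambiguous=ambiguous,
            excluded=bool(reason) or classes[best] == DISCARD_CLASS,
            exclusion_reason=reason or
            (DISCARD_CLASS if classes[best] == DISCARD_CLASS else ""),
        ))
    return preds


def rank_and_pick(
    predictions: list[PhenotypePrediction],
    per_class_quota: int = 200,
    target_classes: list[str] | None = None,
) -> SelectionList:
    """Per class, keep the quota of cells with highest confidence.

    Ordering is stable and fully deterministic: descending confidence,
    then slide id, then nucleus label. Excluded cells (discard class,
    border-touching, user-removed) never enter the ranking. If fewer
    eligible cells than the quota exist, all are returned and the
    shortfall is reported.
    """
    if per_class_quota < 0:
        raise ValueError("quota must be >= 0")
    eligible = [p for p in predictions if not p.excluded]
    known = set().union(*(p.scores.keys() for p in predictions)) if predictions else set()
    if target_classes is None:
        target_classes = sorted(c for c in known if c != DISCARD_CLASS)
    unknown = set(target_classes) - known
    if predictions and unknown:
        raise ValueError(f"unknown class name(s) in quota map: {sorted(unknown)}")
    if any(c == DISCARD_CLASS for c in target_classes):
        raise ValueError("the discard class is never selectable")
    rows = []
    shortfalls: dict[str, int] = {}
    for cls in target_classes:
        cands = [p for p in eligible if p.predicted_class == cls]
        cands.sort(key=lambda p: (-p.confidence, p.slide_id, p.nucleus_label))
        picked = cands[:per_class_quota]
        if len(picked) < per_class_quota:
            shortfalls[cls] = per_class_quota - len(picked)
        for p in picked:
            rows.append({
                "slide_id": p.slide_id, "nucleus_label": p.nucleus_label,
                "class": p.predicted_class, "confidence": p.confidence,
            })
    cells = pd.DataFrame(rows, columns=["slide_id", "nucleus_label", "class",
                                        "confidence"])
    return SelectionList(cells=cells, shortfalls=shortfalls)
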