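"""Reaction-representation evaluation via EC-class discriminant analysis.

Reaction-feature vectors of the same EC class should cluster, because one
enzyme class catalyses one kind of structural change.  This module measures
that with linear discriminant analysis: vectors are classified into EC
classes truncated to 1, 2 or 3 dotted fields, under stratified k-fold
cross-validation (or resubstitution for comparison).  Classes with fewer than
two members are excluded.  Three-digit confusion matrices can be aggregated
up to two digits by summing the corresponding rows and columns, and the
tree, graph and combined latent parts can be compared on identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .errors import ClassError, ParameterError
from .reactions import ReactionFeatureDB, truncate_ec


@dataclass
class ECClassificationReport:
    digit_level: int
    part: str
    classes: list[str]
    confusion: np.ndarray  # rows: true class, cols: predicted
    accuracy: float
    class_counts: dict[str, int]
    folds: int

    @property
    def total(self) -> int:
        return int(self.confusion.sum())


def _eligible(labels: np.ndarray, min_count: int = 2):
    classes, counts = np.unique(labels, return_counts=True)
    keep = classes[counts >= min_count]
    if len(keep) < 2:
        raise ClassError(
            f"need at least 2 EC classes with >= {min_count} members, found {len(keep)}"
        )
    mask = np.isin(labels, keep)
    return mask, sorted(keep)


def classify_ec(
    db: ReactionFeatureDB,
    digit_level: int,
    part: str | None = None,
    folds: int = 5,
    seed: int = 0,
    cross_validate: bool = True,
) -> ECClassificationReport:
    """LDA classification of reaction vectors into EC classes at ``digit_level``.

    Single-member classes are excluded before evaluation.  With
    ``cross_validate`` (default) predictions are pooled over stratified folds
    (the fold count is shrunk to the smallest class size when necessary), so
    every retained vector is predicted exactly once; otherwise the model is
    fit and evaluated on all data (resubstitution).
    """
    if digit_level not in (1, 2, 3):
        raise ParameterError("digit_level must be 1, 2 or 3")
    part = part or db.part
    labels = np.array([truncate_ec(ec, digit_level) for ec in db.ec_numbers()])
    X = db.vector_matrix(part)
    mask, classes = _eligible(labels)
    X, labels = X[mask], labels[mask]
    counts = {c: int(np.sum(labels == c)) for c in classes}

    if cross_validate:
        n_splits = min(folds, min(counts.values()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        pred = np.empty_like(labels)
        for train_idx, test_idx in skf.split(X, labels):
            lda = LinearDiscriminantAnalysis()
            lda.fit(X[train_idx], labels[train_idx])
            pred[test_idx] = lda.predict(X[test_idx])
        used_folds = n_splits
    else:
        lda = LinearDiscriminantAnalysis()
        pred = lda.fit(X, labels).predict(X)
        used_folds = 0

    cm = confusion_matrix(labels, pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum())
    return ECClassificationReport(digit_level, part, list(classes), cm, acc, counts, used_folds)


def aggregate_confusion(report: ECClassificationReport, digit_level: int) -> ECClassificationReport:
    """Sum a finer-grained confusion matrix up to a coarser EC digit level.

    E.g. the three-digit matrix aggregated to two digits: every entry of the
    coarse matrix is the sum of the fine entries whose true/predicted classes
    truncate to the coarse pair.  Totals are conserved.
    """
    if digit_level >= report.digit_level:
        raise ParameterError("target digit_level must be coarser than the report's")
    coarse = sorted({truncate_ec(c, digit_level) for c in report.classes})
    idx = {c: i for i, c in enumerate(coarse)}
    cm = np.zeros((len(coarse), len(coarse)), dtype=report.confusion.dtype)
    for i, ci in enumerate(report.classes):
        for j, cj in enumerate(report.classes):
            cm[idx[truncate_ec(ci, digit_level)], idx[truncate_ec(cj, digit_level)]] += (
                report.confusion[i, j]
            )
    counts: dict[str, int] = {}
    for c, n in report.class_counts.items():
        key = truncate_ec(c, digit_level)
        counts[key] = counts.get(key, 0) + n
    return ECClassificationReport(
        digit_level,
        report.part,
        coarse,
        cm,
        float(np.trace(cm) / cm.sum()),
        counts,
        report.folds,
    )


def compare_parts(
    db: ReactionFeatureDB, digit_level: int = 2, folds: int = 5, seed: int = 0
) -> dict[str, ECClassificationReport]:
    """Classification reports for tree, graph and combined parts on identical folds.

    Requires a combined-part DB so all three sub-vectors are available.  The
    same seed drives the fold shuffle in every part, so splits coincide.
    """
    if db.part != "combined":
        raise ParameterError("compare_parts requires a combined-part DB")
    return {
        part: classify_ec(db, digit_level, part=part, folds=folds, seed=seed)
        for part in ("tree", "graph", "combined")
    }
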