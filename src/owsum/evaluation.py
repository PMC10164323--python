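"""Validation protocol: accuracy rules, k-fold cross-validation, and
under-/over-estimated one-vs-rest ROC AUC and MCC.

Correctness rule: a prediction is correct iff it is a non-empty subset of
the object's true labels.  Unpredictable objects are neither correct nor
incorrect but stay in the overall-accuracy denominator:

* overall accuracy    = correct / all tested objects
* predicted accuracy  = correct / objects where a prediction was made

Because the classifier predicts an argmax set but objects can carry several
true labels, one-vs-rest metrics come in two variants.  Consider a molecule
whose true labels are {floral, perfumery} and whose prediction was {floral};
when scoring the class *perfumery*, the prediction missed it even though it
was globally correct.  The *underestimated* variant keeps that molecule as
a positive with predicted bit 0 (a lower bound on performance); the
*overestimated* variant reassigns it to the rest class, true bit 0 (an
upper bound — at least one true label is indeed in the rest class).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from owsum import model as owm
from owsum.chem import OccurrenceMatrix
from owsum.model import InfluenceModel, PredictionResult
from owsum.records import LabelMatrix

__all__ = [
    "is_correct",
    "accuracies",
    "AccuracySummary",
    "one_vs_rest_labels",
    "roc_auc_binary",
    "mcc_binary",
    "evaluate_predictions",
    "cross_validate",
    "EvaluationReport",
]

logger = logging.getLogger(__name__)


def is_correct(prediction: PredictionResult, true_labels: Iterable[str]) -> bool:
    """True iff a prediction was made and it is a subset of the true labels."""
    true_set = frozenset(true_labels)
    return (
        prediction.status == "predicted"
        and len(prediction.predicted) > 0
        and prediction.predicted <= true_set
    )


@dataclass(frozen=True)
class AccuracySummary:
    overall: float                    # percent, correct / all tested
    predicted: float | None           # percent, correct / all predictable
    nonpredictable: float             # percent of tested objects
    n_tested: int
    n_predictable: int
    n_correct: int


def accuracies(
    predictions: Sequence[PredictionResult],
    truths: Sequence[Iterable[str]],
) -> AccuracySummary:
    """Overall / predicted accuracy and the non-predictable fraction.

    Predicted accuracy is undefined (``None``) when no object was
    predictable.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    n = len(predictions)
    if n == 0:
        raise ValueError("no predictions to evaluate")
    n_correct = sum(
        is_correct(p, t) for p, t in zip(predictions, truths)
    )
    n_predictable = sum(p.status == "predicted" for p in predictions)
    overall = 100.0 * n_correct / n
    predicted = (
        100.0 * n_correct / n_predictable if n_predictable else None
    )
    nonpredictable = 100.0 * (n - n_predictable) / n
    return AccuracySummary(
        overall, predicted, nonpredictable, n, n_predictable, n_correct
    )


def one_vs_rest_labels(
    predictions: Sequence[PredictionResult],
    truths: Sequence[Iterable[str]],
    class_label: str,
    mode: str = "underestimated",
) -> tuple[np.ndarray, np.ndarray]:
    """Binary (true, predicted) vectors for one class under one convention.

    The predicted bit is 1 iff the class is in the object's predicted set
    (0 for unpredictable objects).  The true bit is 1 iff the class is in
    the true set — except for multilabel objects carrying this class whose
    prediction hit a *different* true label: ``underestimated`` keeps
    true=1/pred=0, ``overestimated`` reassigns true=0/pred=0.
    """
    if mode not in ("underestimated", "overestimated"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    t_bits, p_bits = [], []
    for pred, truth in zip(predictions, truths):
        true_set = frozenset(truth)
        p = 1 if class_label in pred.predicted else 0
        t = 1 if class_label in true_set else 0
        if (
            t == 1
            and p == 0
            and len(true_set) > 1
            and pred.predicted & (true_set - {class_label})
        ):
            # prediction was correct via another of the object's labels
            if mode == "overestimated":
                t = 0
        t_bits.append(t)
        p_bits.append(p)
    return np.array(t_bits, dtype=int), np.array(p_bits, dtype=int)


def roc_auc_binary(
    true: Sequence[int], predicted: Sequence[int]
) -> float | None:
    """Rank-based AUC with the hard 0/1 predictions as scores.

    Returns ``None`` when the true vector is constant (AUC undefined); the
    caller excludes such classes from means.
    """
    t = np.asarray(true, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("length mismatch between true and predicted vectors")
    if len(np.unique(t)) < 2:
        logger.info("ROC AUC undefined for constant true vector; skipping")
        return None
    return float(roc_auc_score(t, p))


def mcc_binary(true: Sequence[int], predicted: Sequence[int]) -> float:
    """Matthews correlation with the all-zeros convention.

    If both vectors are entirely zero the classifier correctly assigned
    every object to the rest class and the MCC is defined as 1 (this arises
    only under the overestimated convention).  Other degenerate one-class
    cases return 0.
    """
    t = np.asarray(true, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("length mismatch between true and predicted vectors")
    if not t.any() and not p.any():
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(t, p))


@dataclass
class EvaluationReport:
    """Pooled metrics for one validation run."""

    overall_accuracy: float
    predicted_accuracy: float | None
    nonpredictable: float
    per_class_auc_under: dict[str, float | None]
    per_class_auc_over: dict[str, float | None]
    per_class_mcc_under: dict[str, float]
    per_class_mcc_over: dict[str, float]
    mean_auc_under: float | None
    mean_auc_over: float | None
    mean_mcc_under: float
    mean_mcc_over: float
    n_objects: int
    fold_assignment: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": round(self.overall_accuracy, 1),
            "predicted_accuracy": (
                None if self.predicted_accuracy is None
                else round(self.predicted_accuracy, 1)
            ),
            "nonpredictable": round(self.nonpredictable, 1),
            "mean_auc_underestimated": (
                None if self.mean_auc_under is None
                else round(self.mean_auc_under, 2)
            ),
            "mean_auc_overestimated": (
                None if self.mean_auc_over is None
                else round(self.mean_auc_over, 2)
            ),
            "mean_mcc_underestimated": round(self.mean_mcc_under, 2),
            "mean_mcc_overestimated": round(self.mean_mcc_over, 2),
            "per_class": {
                c: {
                    "auc_underestimated": self.per_class_auc_under[c],
                    "auc_overestimated": self.per_class_auc_over[c],
                    "mcc_underestimated": self.per_class_mcc_under[c],
                    "mcc_overestimated": self.per_class_mcc_over[c],
                }
                for c in self.per_class_auc_under
            },
            "n_objects": self.n_objects,
            "seed": self.seed,
            "fold_assignment": self.fold_assignment,
            "config": self.config,
        }


def evaluate_predictions(
    predictions: Sequence[PredictionResult],
    truths: Sequence[Iterable[str]],
    classes: Sequence[str],
) -> EvaluationReport:
    """Accuracies plus per-class and mean under/over AUC and MCC."""
    acc = accuracies(predictions, truths)
    auc_u: dict[str, float | None] = {}
    auc_o: dict[str, float | None] = {}
    mcc_u: dict[str, float] = {}
    mcc_o: dict[str, float] = {}
    for c in classes:
        tu, pu = one_vs_rest_labels(predictions, truths, c, "underestimated")
        to, po = one_vs_rest_labels(predictions, truths, c, "overestimated")
        auc_u[c] = roc_auc_binary(tu, pu)
        auc_o[c] = roc_auc_binary(to, po)
        mcc_u[c] = mcc_binary(tu, pu)
        mcc_o[c] = mcc_binary(to, po)

    def _mean(vals: Iterable[float | None]) -> float | None:
        defined = [v for v in vals if v is not None]
        return float(np.mean(defined)) if defined else None

    return EvaluationReport(
        overall_accuracy=acc.overall,
        predicted_accuracy=acc.predicted,
        nonpredictable=acc.nonpredictable,
        per_class_auc_under=auc_u,
        per_class_auc_over=auc_o,
        per_class_mcc_under=mcc_u,
        per_class_mcc_over=mcc_o,
        mean_auc_under=_mean(auc_u.values()),
        mean_auc_over=_mean(auc_o.values()),
        mean_mcc_under=float(np.mean(list(mcc_u.values()))),
        mean_mcc_over=float(np.mean(list(mcc_o.values()))),
        n_objects=acc.n_tested,
    )


def _fold_indices(n: int, k: int, seed: int | None) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def cross_validate(
    occ: OccurrenceMatrix,
    labels: LabelMatrix,
    variant: str = "tfidf_weighted",
    feature_selection: bool = True,
    k: int | None = 5,
    seed: int | None = 0,
    log_base: float = math.e,
) -> EvaluationReport:
    """k-fold cross-validation of the classifier.

    Objects are shuffled with ``seed`` and split into ``k`` near-equal
    folds; the model (including idf and feature selection) is refit on each
    training split and evaluated on the held-out fold.  Metrics are pooled
    over all held-out predictions and then averaged across classes.

    ``k=None`` trains and tests on the whole dataset (training accuracy).
    A class absent from some training split is dropped from that fold's
    model with a warning; the held-out objects can then never be predicted
    as that class.
    """
    if occ.object_ids != labels.object_ids:
        raise ValueError("occurrence and label matrices must align")
    n = len(occ.object_ids)
    fold_assignment: dict[str, int] = {}
    predictions: list[PredictionResult] = []
    truth_sets = labels.truth_sets()
    truths: list[frozenset[str]] = []

    if k is None:
        model = owm.fit(
            occ, labels, variant=variant,
            feature_selection=feature_selection, log_base=log_base,
        )
        predictions = owm.predict(occ, model)
        truths = truth_sets
        fold_assignment = {oid: 0 for oid in occ.object_ids}
    else:
        if k < 2:
            raise ValueError("k must be >= 2 (or None for train=test)")
        if n < k:
            raise ValueError(f"dataset of {n} objects cannot be split into {k} folds")
        folds = _fold_indices(n, k, seed)
        for fold_no, test_idx in enumerate(folds):
            test_set = set(int(i) for i in test_idx)
            train_idx = [i for i in range(n) if i not in test_set]
            occ_tr = occ.subset(train_idx)
            lab_tr = labels.subset(train_idx)
            present = lab_tr.values.sum(axis=0) > 0
            if not present.all():
                missing = [
                    c for c, p in zip(labels.classes, present) if not p
                ]
                logger.warning(
                    "fold %d: classes %s absent from training split; "
                    "they cannot be predicted in this fold", fold_no, missing,
                )
                keep = [c for c in labels.classes if c not in missing]
                lab_tr = LabelMatrix(
                    lab_tr.object_ids, tuple(keep),
                    lab_tr.values[:, present],
                )
            model = owm.fit(
                occ_tr, lab_tr, variant=variant,
                feature_selection=feature_selection, log_base=log_base,
            )
            occ_te = occ.subset(sorted(test_set))
            for pred, row in zip(owm.predict(occ_te, model), sorted(test_set)):
                predictions.append(pred)
                truths.append(truth_sets[row])
                fold_assignment[pred.object_id] = fold_no

    report = evaluate_predictions(predictions, truths, labels.classes)
    report.fold_assignment = fold_assignment
    report.seed = seed
    report.config = {
        "variant": variant,
        "feature_selection": feature_selection,
        "k": k,
        "log_base": log_base,
    }
    return report
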