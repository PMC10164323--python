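"""The weighted-sum classifier: conditional-probability weights, tf-idf
weighting, influence matrices, scoring and argmax-set prediction.

The model is linear and fully interpretable.  For feature ``F_j`` and class
``C_i``:

* weight        ``G[i,j] = Pr(F_j | C_i)`` — fraction of class members
  containing the feature (counted on training data);
* idf           ``idf[j] = log(|C| / #classes containing F_j)`` — feature
  specificity across classes;
* tf-idf        ``tfidf[i,j] = G[i,j] * idf[j]`` — the within-class term
  frequency equals ``G`` by definition, since occurrence is binary;
* influence     ``I[i,j] = a[i,j] * G[i,j]`` with the weighting factor ``a``
  set by the model variant.

An object's score for a class is the sum of the influences of the selected,
trained features it contains.  The predicted label set is the argmax set; an
object with no usable features, or whose argmax set spans every class, is
*unpredictable*.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from owsum.chem import OccurrenceMatrix
from owsum.records import LabelMatrix

__all__ = [
    "VARIANTS",
    "TrainingError",
    "InfluenceModel",
    "PredictionResult",
    "compute_weights",
    "compute_idf",
    "compute_tfidf",
    "fit",
    "score",
    "predict_from_scores",
    "rank_features",
    "influence_difference",
    "save_model",
    "load_model",
]

VARIANTS = (
    "same_weighted",
    "tfidf_weighted",
    "tfidf_over_prfc",
    "tfidf_over_prfc_times_prcf",
)


class TrainingError(ValueError):
    """Raised for unusable training input (e.g. an empty class)."""


def _check_aligned(occ: OccurrenceMatrix, labels: LabelMatrix) -> None:
    if occ.object_ids != labels.object_ids:
        raise TrainingError(
            "occurrence and label matrices must share identically ordered "
            "object ids"
        )


def _counts(occ: OccurrenceMatrix, labels: LabelMatrix) -> np.ndarray:
    """Class x feature co-occurrence counts #(F_j, C_i)."""
    return labels.values.T.astype(np.int64) @ occ.values.astype(np.int64)


def compute_weights(occ: OccurrenceMatrix, labels: LabelMatrix) -> np.ndarray:
    """Conditional-probability weight matrix G, class x feature.

    ``G[i,j]`` is the fraction of class-``i`` training objects that contain
    feature ``j``; a multilabel object contributes to every class it belongs
    to.  Raises :class:`TrainingError` naming any empty class.
    """
    _check_aligned(occ, labels)
    sizes = labels.class_sizes()
    empty = [c for c, n in zip(labels.classes, sizes) if n == 0]
    if empty:
        raise TrainingError(f"classes without training members: {empty}")
    return _counts(occ, labels) / sizes[:, None]


def compute_idf(
    occ: OccurrenceMatrix, labels: LabelMatrix, log_base: float = math.e
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature inverse document frequency over classes.

    ``idf[j] = log(|C| / #classes with at least one member containing F_j)``.
    Features absent from every training object have no defined idf; they are
    returned as 0 with ``trained[j] = False`` and must be excluded from the
    model.  Returns ``(idf, trained)``.
    """
    _check_aligned(occ, labels)
    n_classes = len(labels.classes)
    class_has = _counts(occ, labels) > 0
    n_classes_with = class_has.sum(axis=0)
    trained = occ.values.sum(axis=0) > 0
    idf = np.zeros(len(occ.patterns), dtype=float)
    nz = trained
    idf[nz] = np.log(n_classes / n_classes_with[nz]) / math.log(log_base)
    return idf, trained


def compute_tfidf(
    occ: OccurrenceMatrix, labels: LabelMatrix, log_base: float = math.e
) -> np.ndarray:
    """Class x feature tf-idf matrix.

    The term frequency ``#(F_j, C_i) / len(C_i)`` coincides with ``G`` since
    occurrence is binary, so ``tfidf = G * idf`` elementwise.
    """
    sizes = labels.class_sizes()
    if (sizes == 0).any():
        raise TrainingError("tf-idf undefined for empty classes")
    tf = _counts(occ, labels) / sizes[:, None]
    idf, _ = compute_idf(occ, labels, log_base=log_base)
    return tf * idf[None, :]


@dataclass(frozen=True)
class InfluenceModel:
    """Trained classifier state: weights, idf, influences and metadata."""

    classes: tuple[str, ...]
    patterns: tuple[str, ...]
    G: np.ndarray                 # class x feature, Pr(F|C)
    idf: np.ndarray               # per feature
    tfidf: np.ndarray             # class x feature
    a: np.ndarray                 # class x feature weighting factors
    influence: np.ndarray         # class x feature, a * G
    selected: np.ndarray          # per-feature bool mask
    trained: np.ndarray           # per-feature bool: seen in training data
    variant: str
    class_sizes: np.ndarray
    feature_selection: bool
    log_base: float = math.e

    def class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"unknown class {label!r}") from None


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of classifying one object.

    ``status`` is ``"predicted"`` when the argmax set is a non-empty proper
    subset of the classes, else ``"unpredictable"`` (no usable features, or
    the argmax set spans every class) with an empty predicted set.
    """

    object_id: str
    scores: Mapping[str, float]
    predicted: frozenset[str]
    status: str
    used_features: int = 0

    @property
    def is_predictable(self) -> bool:
        return self.status == "predicted"


def fit(
    occ: OccurrenceMatrix,
    labels: LabelMatrix,
    variant: str = "tfidf_weighted",
    feature_selection: bool = True,
    log_base: float = math.e,
) -> InfluenceModel:
    """Train the classifier on a binary occurrence and label matrix.

    ``variant`` picks the weighting factor ``a``:

    ==============================  =============================================
    same_weighted                   ``a = 1`` (influence is the raw weight G)
    tfidf_weighted                  ``a = tfidf`` (influence ``G^2 * idf``)
    tfidf_over_prfc                 ``a = tfidf / G`` (influence equals tf-idf)
    tfidf_over_prfc_times_prcf      ``a = tfidf * Pr(C|F) / G``
    ==============================  =============================================

    The division variants are defined as their limits where ``G = 0``, i.e.
    zero influence.  With ``feature_selection`` enabled, features whose idf
    is zero (present in every class) are dropped from scoring.
    """
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    G = compute_weights(occ, labels)
    idf, trained = compute_idf(occ, labels, log_base=log_base)
    sizes = labels.class_sizes()
    tfidf = G * idf[None, :]
    counts = _counts(occ, labels)
    feature_totals = occ.values.sum(axis=0).astype(np.int64)

    if variant == "same_weighted":
        a = np.ones_like(G)
    elif variant == "tfidf_weighted":
        a = tfidf
    elif variant == "tfidf_over_prfc":
        # tfidf / G simplifies to idf wherever G > 0; limit 0 at G = 0.
        a = np.where(G > 0, idf[None, :], 0.0)
    else:  # tfidf_over_prfc_times_prcf
        with np.errstate(divide="ignore", invalid="ignore"):
            prcf = np.where(
                feature_totals[None, :] > 0,
                counts / np.maximum(feature_totals[None, :], 1),
                0.0,
            )
        a = np.where(G > 0, idf[None, :] * prcf, 0.0)

    influence = a * G
    if feature_selection:
        selected = trained & (idf > 0)
    else:
        selected = trained.copy()
    return InfluenceModel(
        classes=labels.classes,
        patterns=occ.patterns,
        G=G,
        idf=idf,
        tfidf=tfidf,
        a=a,
        influence=influence,
        selected=selected,
        trained=trained,
        variant=variant,
        class_sizes=sizes,
        feature_selection=feature_selection,
        log_base=log_base,
    )


def score(
    feature_vector: np.ndarray, model: InfluenceModel
) -> tuple[np.ndarray, int]:
    """Per-class scores for one object plus the count of usable features.

    ``S[i]`` sums the influences of every feature that is present in the
    object, selected, and seen in training.  Features the model never
    trained on contribute nothing.
    """
    fvec = np.asarray(feature_vector, dtype=np.uint8)
    if fvec.shape != (len(model.patterns),):
        raise ValueError(
            f"feature vector length {fvec.shape} does not match the model's "
            f"{len(model.patterns)} patterns"
        )
    usable = (fvec == 1) & model.selected
    scores = model.influence[:, usable].sum(axis=1)
    return scores, int(usable.sum())


def predict_from_scores(
    object_id: str,
    scores: Mapping[str, float] | Sequence[float],
    classes: Sequence[str] | None = None,
    used_features: int = 1,
) -> PredictionResult:
    """Turn per-class scores into an argmax-set prediction.

    All classes attaining the maximal score are predicted.  If the object
    used no trained features, or the argmax set equals the full class set,
    the object is unpredictable and the predicted set is empty.
    """
    if isinstance(scores, Mapping):
        classes = tuple(scores.keys())
        vec = np.array([scores[c] for c in classes], dtype=float)
    else:
        if classes is None:
            raise ValueError("classes required when scores is a sequence")
        classes = tuple(classes)
        vec = np.asarray(scores, dtype=float)
    score_map = {c: float(s) for c, s in zip(classes, vec)}
    argmax = frozenset(
        c for c, s in zip(classes, vec) if s == vec.max()
    )
    if used_features == 0 or len(argmax) == len(classes):
        return PredictionResult(
            object_id, score_map, frozenset(), "unpredictable",
            used_features=used_features,
        )
    return PredictionResult(
        object_id, score_map, argmax, "predicted", used_features=used_features
    )


def predict(
    occ: OccurrenceMatrix, model: InfluenceModel
) -> list[PredictionResult]:
    """Classify every row of an occurrence matrix."""
    if occ.patterns != model.patterns:
        raise ValueError(
            "occurrence matrix patterns do not match the model catalog"
        )
    out = []
    for k, oid in enumerate(occ.object_ids):
        s, used = score(occ.values[k], model)
        out.append(
            predict_from_scores(oid, s, model.classes, used_features=used)
        )
    return out


def rank_features(
    model: InfluenceModel, class_label: str
) -> list[tuple[str, float]]:
    """Selected features sorted by descending influence for a class.

    Ties keep catalog order, so equal-influence features stay grouped and
    the ranking is deterministic.
    """
    i = model.class_index(class_label)
    entries = [
        (p, float(model.influence[i, j]))
        for j, p in enumerate(model.patterns)
        if model.selected[j]
    ]
    entries.sort(key=lambda t: -t[1])
    return entries


def influence_difference(
    model: InfluenceModel, class_a: str, class_b: str
) -> list[tuple[str, float]]:
    """Signed per-feature influence differences ``I[a] - I[b]``.

    Sorted by descending difference: the top of the list is most
    characteristic of ``class_a``, the bottom of ``class_b``.  Identical
    class arguments give all zeros (valid degenerate case).
    """
    ia = model.class_index(class_a)
    ib = model.class_index(class_b)
    diff = model.influence[ia] - model.influence[ib]
    entries = [
        (p, float(diff[j]))
        for j, p in enumerate(model.patterns)
        if model.selected[j]
    ]
    entries.sort(key=lambda t: -t[1])
    return entries


def _catalog_hash(patterns: Sequence[str]) -> str:
    h = hashlib.sha256()
    for p in patterns:
        h.update(p.encode("utf-8"))
        h.update(b"\n")
    return h.hexdigest()[:16]


def save_model(model: InfluenceModel, path: str | Path) -> None:
    """Serialize as a per-(class, feature) TSV plus a JSON header.

    Columns: ``class smarts G idf tfidf a influence selected``.  The header
    (``<path>.meta.json``) records variant, class sizes, log base and a
    catalog hash so the model can be reloaded for prediction without
    retraining.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("class\tsmarts\tG\tidf\ttfidf\ta\tinfluence\tselected\n")
        for i, c in enumerate(model.classes):
            for j, p in enumerate(model.patterns):
                fh.write(
                    f"{c}\t{p}\t{model.G[i, j]:.10g}\t{model.idf[j]:.10g}\t"
                    f"{model.tfidf[i, j]:.10g}\t{model.a[i, j]:.10g}\t"
                    f"{model.influence[i, j]:.10g}\t"
                    f"{int(model.selected[j])}\n"
                )
    meta = {
        "variant": model.variant,
        "classes": list(model.classes),
        "class_sizes": [int(n) for n in model.class_sizes],
        "patterns": list(model.patterns),
        "trained": [bool(t) for t in model.trained],
        "feature_selection": model.feature_selection,
        "log_base": model.log_base,
        "catalog_hash": _catalog_hash(model.patterns),
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, indent=1), encoding="utf-8"
    )


def load_model(path: str | Path) -> InfluenceModel:
    path = Path(path)
    meta = json.loads(
        Path(str(path) + ".meta.json").read_text(encoding="utf-8")
    )
    classes = tuple(meta["classes"])
    patterns = tuple(meta["patterns"])
    ci = {c: i for i, c in enumerate(classes)}
    pj = {p: j for j, p in enumerate(patterns)}
    shape = (len(classes), len(patterns))
    G = np.zeros(shape)
    tfidf = np.zeros(shape)
    a = np.zeros(shape)
    influence = np.zeros(shape)
    idf = np.zeros(len(patterns))
    selected = np.zeros(len(patterns), dtype=bool)
    lines = path.read_text(encoding="utf-8").splitlines()[1:]
    for ln in lines:
        c, p, g, d, t, aa, inf, sel = ln.split("\t")
        i, j = ci[c], pj[p]
        G[i, j] = float(g)
        idf[j] = float(d)
        tfidf[i, j] = float(t)
        a[i, j] = float(aa)
        influence[i, j] = float(inf)
        selected[j] = bool(int(sel))
    return InfluenceModel(
        classes=classes,
        patterns=patterns,
        G=G,
        idf=idf,
        tfidf=tfidf,
        a=a,
        influence=influence,
        selected=selected,
        trained=np.array(meta["trained"], dtype=bool),
        variant=meta["variant"],
        class_sizes=np.array(meta["class_sizes"], dtype=np.int64),
        feature_selection=bool(meta["feature_selection"]),
        log_base=float(meta["log_base"]),
    )
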