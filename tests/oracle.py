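"""Independent brute-force oracles used to check the implementation.

Everything here is computed by plain-Python counting and enumeration over
dictionaries and lists — no numpy, no shared code paths with the package —
so agreement with the library is a genuine dual-route check.
"""

from __future__ import annotations

import math


def oracle_counts(occ_rows, label_rows):
    """occ_rows: list of lists 0/1; label_rows: list of lists 0/1."""
    n_cls = len(label_rows[0])
    n_feat = len(occ_rows[0])
    counts = [[0] * n_feat for _ in range(n_cls)]
    for obj_feats, obj_labels in zip(occ_rows, label_rows):
        for i in range(n_cls):
            if obj_labels[i]:
                for j in range(n_feat):
                    if obj_feats[j]:
                        counts[i][j] += 1
    return counts


def oracle_model(occ_rows, label_rows, variant, feature_selection,
                 log_base=math.e):
    """Counting-based model: returns dict with G, idf, tfidf, a, I, masks."""
    n_obj = len(occ_rows)
    n_cls = len(label_rows[0])
    n_feat = len(occ_rows[0])
    sizes = [sum(label_rows[k][i] for k in range(n_obj)) for i in range(n_cls)]
    counts = oracle_counts(occ_rows, label_rows)
    feat_totals = [
        sum(occ_rows[k][j] for k in range(n_obj)) for j in range(n_feat)
    ]
    trained = [feat_totals[j] > 0 for j in range(n_feat)]

    G = [[counts[i][j] / sizes[i] for j in range(n_feat)]
         for i in range(n_cls)]
    idf = []
    for j in range(n_feat):
        if not trained[j]:
            idf.append(0.0)
            continue
        n_classes_with = sum(1 for i in range(n_cls) if counts[i][j] > 0)
        idf.append(math.log(n_cls / n_classes_with) / math.log(log_base))
    tfidf = [[G[i][j] * idf[j] for j in range(n_feat)] for i in range(n_cls)]

    a = [[0.0] * n_feat for _ in range(n_cls)]
    for i in range(n_cls):
        for j in range(n_feat):
            if variant == "same_weighted":
                a[i][j] = 1.0
            elif variant == "tfidf_weighted":
                a[i][j] = tfidf[i][j]
            elif variant == "tfidf_over_prfc":
                a[i][j] = idf[j] if G[i][j] > 0 else 0.0
            elif variant == "tfidf_over_prfc_times_prcf":
                if G[i][j] > 0:
                    prcf = counts[i][j] / feat_totals[j]
                    a[i][j] = idf[j] * prcf
            else:
                raise ValueError(variant)
    influence = [[a[i][j] * G[i][j] for j in range(n_feat)]
                 for i in range(n_cls)]
    if feature_selection:
        selected = [trained[j] and idf[j] > 0 for j in range(n_feat)]
    else:
        selected = list(trained)
    return {
        "G": G, "idf": idf, "tfidf": tfidf, "a": a, "influence": influence,
        "selected": selected, "trained": trained,
    }


def oracle_scores(feature_vector, oracle):
    """Sequential per-class influence sums over usable features."""
    n_cls = len(oracle["influence"])
    scores = []
    used = sum(
        1 for j, f in enumerate(feature_vector)
        if f and oracle["selected"][j]
    )
    for i in range(n_cls):
        s = 0.0
        for j, f in enumerate(feature_vector):
            if f and oracle["selected"][j]:
                s += oracle["influence"][i][j]
        scores.append(s)
    return scores, used


def oracle_predicted_set(scores, classes, used):
    """Argmax-set rule: unpredictable on no features or a full-set argmax."""
    mx = max(scores)
    argmax = {c for c, s in zip(classes, scores) if s == mx}
    if used == 0 or len(argmax) == len(classes):
        return frozenset(), "unpredictable"
    return frozenset(argmax), "predicted"


def oracle_auc(true, pred):
    """Pairwise win/tie enumeration over all positive-negative pairs."""
    pos = [p for t, p in zip(true, pred) if t == 1]
    neg = [p for t, p in zip(true, pred) if t == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_mcc(true, pred):
    """Confusion-table arithmetic with the all-zeros-is-1 convention."""
    if not any(true) and not any(pred):
        return 1.0
    tp = sum(1 for t, p in zip(true, pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(true, pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(true, pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(true, pred) if t == 1 and p == 0)
    denom = math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom
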