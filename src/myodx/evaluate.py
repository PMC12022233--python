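"""Class-imbalance-aware evaluation of ranked multiclass predictions.

Core metric: the class-weighted top-n accuracy

    W_n = sum_i w_{y_i} * I(y_i in P_{n,i}) / sum_i w_{y_i},

where P_{n,i} are the n classes with the highest predicted probability for
sample i and the weights are inverse class frequencies, w_c = S / count(c).
W_1 coincides with balanced accuracy (the unweighted mean of per-class
recalls), and W_K is identically 1.

Curves: one-vs-rest ROC and precision-recall per class with micro and macro
averages, plus a pairwise (one-vs-one) AUPRC matrix where each class pair is
evaluated in both directions on its own samples and the two areas averaged.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import (
    auc,
    balanced_accuracy_score,
    confusion_matrix as _sk_confusion,
    precision_recall_curve,
    roc_curve,
)


def class_weights(labels) -> dict:
    """Inverse-frequency weights: w_c = S / count(c)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    classes, counts = np.unique(labels, return_counts=True)
    total = labels.size
    return {c: total / n for c, n in zip(classes, counts)}


def top_n_sets(probabilities: np.ndarray, classes, n: int) -> np.ndarray:
    """Top-n predicted classes per row, descending probability; probability
    ties broken by fixed class order (column position)."""
    probabilities = np.asarray(probabilities, dtype=float)
    classes = np.asarray(classes)
    k = probabilities.shape[1]
    if not 1 <= n <= k:
        raise ValueError(f"n must be in [1, {k}], got {n}")
    order = np.argsort(-probabilities, axis=1, kind="stable")
    return classes[order[:, :n]]


def weighted_topn(y_true, probabilities, n: int, classes=None) -> float:
    """Class-weighted top-n accuracy W_n in [0, 1]."""
    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    if probabilities.shape != (y_true.size, classes.size):
        raise ValueError("probability matrix does not align with labels")
    weights = class_weights(y_true)
    w = np.array([weights[c] for c in y_true])
    top = top_n_sets(probabilities, classes, n)
    hits = np.array([y in row for y, row in zip(y_true, top)])
    return float(np.sum(w * hits) / np.sum(w))


def topn_accuracy(y_true, probabilities, n: int, classes=None) -> float:
    """Unweighted top-n accuracy (fraction of samples with the truth in the
    top n), for comparison alongside W_n."""
    y_true = np.asarray(y_true)
    if classes is None:
        classes = np.unique(y_true)
    top = top_n_sets(np.asarray(probabilities, float), np.asarray(classes), n)
    return float(np.mean([y in row for y, row in zip(y_true, top)]))


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recalls."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    if y_true.size == 0:
        raise ValueError("empty labels")
    return float(balanced_accuracy_score(y_true, y_pred))


def confusion(y_true, y_pred, normalize: str = "none",
              classes=None) -> tuple[np.ndarray, np.ndarray]:
    """Confusion matrix (rows = ground truth).  ``normalize="truth"``
    divides each row by its ground-truth count so rows sum to 1."""
    if normalize not in ("none", "truth"):
        raise ValueError(f"normalize must be 'none' or 'truth', got {normalize!r}")
    if classes is None:
        classes = np.unique(np.concatenate([np.asarray(y_true), np.asarray(y_pred)]))
    classes = np.asarray(classes)
    mat = _sk_confusion(y_true, y_pred, labels=classes).astype(float)
    if normalize == "truth":
        sums = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)
    return mat, classes


def _step_auprc(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise interpolation:
    precision is held at its value over each recall increment."""
    precision, recall, _ = precision_recall_curve(y_bin, scores)
    # curve arrives in decreasing-recall order; integrate the steps
    return float(-np.sum(np.diff(recall) * precision[:-1]))


def ovr_curves(y_true, probabilities, classes=None) -> dict:
    """One-vs-rest ROC and PRC per class plus micro/macro aggregates.

    Classes without positive samples are skipped (with a warning) and
    excluded from the macro averages.
    """
    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    if probabilities.shape[1] != classes.size:
        raise ValueError("probability columns do not match classes")
    if classes.size < 2:
        raise ValueError("need at least two classes")
    per_class = {}
    for j, c in enumerate(classes):
        y_bin = (y_true == c).astype(int)
        if y_bin.sum() == 0:
            warnings.warn(f"class {c!r} has no positive samples; skipped")
            continue
        fpr, tpr, _ = roc_curve(y_bin, probabilities[:, j])
        per_class[c] = {
            "roc": (fpr, tpr),
            "auroc": float(auc(fpr, tpr)),
            "prc": precision_recall_curve(y_bin, probabilities[:, j])[:2],
            "auprc": _step_auprc(y_bin, probabilities[:, j]),
        }
    onehot = (y_true[:, None] == classes[None, :]).astype(int)
    micro_fpr, micro_tpr, _ = roc_curve(onehot.ravel(), probabilities.ravel())
    result = {
        "per_class": per_class,
        "micro": {
            "auroc": float(auc(micro_fpr, micro_tpr)),
            "auprc": _step_auprc(onehot.ravel(), probabilities.ravel()),
        },
        "macro": {
            "auroc": float(np.mean([v["auroc"] for v in per_class.values()])),
            "auprc": float(np.mean([v["auprc"] for v in per_class.values()])),
        },
    }
    return result


def ovo_prc(y_true, probabilities, classes=None) -> np.ndarray:
    """Pairwise AUPRC matrix, symmetric by construction.

    For each class pair the evaluation restricts to samples of the two
    classes, renormalizes the pair's probabilities, computes AUPRC twice
    (each class as positive) and averages.  Pairs missing a class get NaN.
    """
    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    k = classes.size
    out = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a + 1, k):
            mask = (y_true == classes[a]) | (y_true == classes[b])
            if not ((y_true[mask] == classes[a]).any()
                    and (y_true[mask] == classes[b]).any()):
                warnings.warn(
                    f"pair ({classes[a]!r}, {classes[b]!r}) misses a class")
                continue
            pair = probabilities[mask][:, [a, b]]
            denom = pair.sum(axis=1, keepdims=True)
            denom[denom == 0] = 1.0
            pair = pair / denom
            y_pair = y_true[mask]
            auprc_a = _step_auprc((y_pair == classes[a]).astype(int), pair[:, 0])
            auprc_b = _step_auprc((y_pair == classes[b]).astype(int), pair[:, 1])
            out[a, b] = out[b, a] = 0.5 * (auprc_a + auprc_b)
    return out


def metrics_report(y_true, probabilities, classes=None,
                   top_ns=(1, 3, 5)) -> dict:
    """JSON-ready summary: balanced accuracy, W_n (and unweighted top-n),
    per-class recall/AUPRC, truth-normalized confusion matrix."""
    y_true = np.asarray(y_true)
    probabilities = np.asarray(probabilities, dtype=float)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    y_pred = classes[np.argmax(probabilities, axis=1)]
    conf, _ = confusion(y_true, y_pred, normalize="truth", classes=classes)
    curves = ovr_curves(y_true, probabilities, classes)
    report = {
        "balanced_accuracy": balanced_accuracy(y_true, y_pred),
        "weighted_topn": {
            f"W{n}": weighted_topn(y_true, probabilities, min(n, classes.size),
                                   classes)
            for n in top_ns
        },
        "topn": {
            f"top{n}": topn_accuracy(y_true, probabilities,
                                     min(n, classes.size), classes)
            for n in top_ns
        },
        "auprc_micro": curves["micro"]["auprc"],
        "auprc_macro": curves["macro"]["auprc"],
        "auroc_micro": curves["micro"]["auroc"],
        "auroc_macro": curves["macro"]["auroc"],
        "per_class": {
            str(c): {
                "recall": float(conf[i, i]),
                "auprc": curves["per_class"].get(c, {}).get("auprc"),
            }
            for i, c in enumerate(classes)
        },
        "confusion_truth_normalized": conf.tolist(),
        "classes": [str(c) for c in classes],
    }
    return report
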