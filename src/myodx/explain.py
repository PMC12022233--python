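"""SHAP-based pattern discovery for the boosted ensemble.

Attributions are tree-SHAP values computed on the raw margin scale of each
member and averaged across members — exactly mirroring how the ensemble
averages margins, so local accuracy (base value + sum of attributions =
averaged margin) carries over to the ensemble.  Pairwise SHAP interaction
values decompose each attribution into a main effect (diagonal) and
synergies (off-diagonal); summing an interaction row recovers the SHAP
value.

Summaries: per-disease mean |SHAP| matrices with hierarchical clustering of
rows and columns, per-disease interaction heatmaps with the diagonal zeroed
(main effects would otherwise dominate the colour scale), dependence
scatters for a feature pair, and per-sample waterfall orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .ensemble import XGBEnsembleClassifier


@dataclass
class ShapTensor:
    """values: samples x classes x features (margin scale); base_values: per
    class expected margin; features/feature_names kept for colouring."""

    values: np.ndarray
    base_values: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    classes: np.ndarray

    def margins(self) -> np.ndarray:
        """Reconstructed ensemble margins: base + sum of attributions."""
        return self.base_values[None, :] + self.values.sum(axis=2)


@dataclass
class InteractionTensor:
    """values: samples x classes x features x features; the diagonal holds
    main effects.  Symmetric in the two feature axes."""

    values: np.ndarray
    base_values: np.ndarray
    features: np.ndarray
    feature_names: list[str]
    classes: np.ndarray

    def shap_values(self) -> np.ndarray:
        """Row-sums over one feature axis recover plain SHAP values."""
        return self.values.sum(axis=3)


def _member_contribs(model: XGBEnsembleClassifier, X: np.ndarray,
                     interactions: bool) -> np.ndarray:
    dm = xgb.DMatrix(np.asarray(X, dtype=float))
    outs = []
    for booster in model.members_:
        out = booster.predict(dm, pred_interactions=interactions,
                              pred_contribs=not interactions)
        outs.append(out)
    return np.mean(outs, axis=0)


def _check_features(model: XGBEnsembleClassifier, X,
                    feature_names: list[str] | None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature matrix shape {X.shape} does not match the model's "
            f"{model.n_features_in_} features")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    return X, list(names)


def compute_shap(model: XGBEnsembleClassifier, X,
                 feature_names: list[str] | None = None) -> ShapTensor:
    """Tree-SHAP attributions of the ensemble's raw margins."""
    X, names = _check_features(model, X, feature_names)
    contribs = _member_contribs(model, X, interactions=False)
    # xgboost returns samples x classes x (features + bias)
    values = contribs[:, :, :-1]
    base = contribs[0, :, -1]
    return ShapTensor(values=values, base_values=base, features=X,
                      feature_names=names, classes=model.classes_)


def compute_interactions(model: XGBEnsembleClassifier, X,
                         feature_names: list[str] | None = None
                         ) -> InteractionTensor:
    """Pairwise SHAP interaction values (quadratic in feature count)."""
    X, names = _check_features(model, X, feature_names)
    inter = _member_contribs(model, X, interactions=True)
    values = inter[:, :, :-1, :-1]
    base = inter[0, :, -1, -1]
    return InteractionTensor(values=values, base_values=base, features=X,
                             feature_names=names, classes=model.classes_)


def _cluster_order(matrix: np.ndarray) -> np.ndarray:
    """Leaf order of average-linkage Euclidean clustering of the rows."""
    if matrix.shape[0] < 3:
        return np.arange(matrix.shape[0])
    link = linkage(pdist(matrix, metric="euclidean"), method="average")
    return leaves_list(link)


def mean_abs_shap(tensor: ShapTensor, y_true=None,
                  mode: str = "all") -> tuple[pd.DataFrame, dict]:
    """Disease x feature matrix of mean absolute SHAP values, clustered.

    ``mode="all"`` (default) averages every sample's attribution toward each
    class; ``mode="class-only"`` restricts each row to the samples whose
    ground truth is that class (requires ``y_true``).
    Returns ``(matrix, {"row_order": [...], "col_order": [...]})`` with the
    DataFrame already ordered by the clustering.
    """
    if mode not in ("all", "class-only"):
        raise ValueError(f"mode must be 'all' or 'class-only', got {mode!r}")
    rows = []
    kept = []
    for j, cls in enumerate(tensor.classes):
        if mode == "class-only":
            if y_true is None:
                raise ValueError("class-only mode needs y_true")
            mask = np.asarray(y_true) == cls
            if not mask.any():
                continue
            rows.append(np.abs(tensor.values[mask, j, :]).mean(axis=0))
        else:
            rows.append(np.abs(tensor.values[:, j, :]).mean(axis=0))
        kept.append(cls)
    matrix = pd.DataFrame(np.array(rows), index=[str(c) for c in kept],
                          columns=tensor.feature_names)
    row_order = _cluster_order(matrix.to_numpy())
    col_order = _cluster_order(matrix.to_numpy().T)
    ordered = matrix.iloc[row_order, col_order]
    orders = {"row_order": [matrix.index[i] for i in row_order],
              "col_order": [matrix.columns[i] for i in col_order]}
    return ordered, orders


def top_features(tensor: ShapTensor, disease, n: int = 5,
                 y_true=None, mode: str = "all",
                 among: list[str] | None = None) -> list[str]:
    """The n features with the largest mean |SHAP| toward ``disease``.

    ``among`` restricts the ranking to a subset of features, e.g. to the
    muscle columns when comparing against a muscle involvement pattern
    (asymmetry/age/sex features otherwise compete for the top ranks).
    """
    j = list(map(str, tensor.classes)).index(str(disease))
    if mode == "class-only":
        mask = np.asarray(y_true) == tensor.classes[j]
        scores = np.abs(tensor.values[mask, j, :]).mean(axis=0)
    else:
        scores = np.abs(tensor.values[:, j, :]).mean(axis=0)
    order = np.argsort(-scores, kind="stable")
    pool = set(among) if among is not None else None
    names = [tensor.feature_names[i] for i in order
             if pool is None or tensor.feature_names[i] in pool]
    return names[:n]


def interaction_summary(tensor: InteractionTensor,
                        disease) -> tuple[pd.DataFrame, dict]:
    """Clustered feature x feature mean |interaction| matrix for a disease,
    with the diagonal (main effects) set to zero before clustering."""
    j = list(map(str, tensor.classes)).index(str(disease))
    matrix = np.abs(tensor.values[:, j, :, :]).mean(axis=0)
    np.fill_diagonal(matrix, 0.0)
    frame = pd.DataFrame(matrix, index=tensor.feature_names,
                         columns=tensor.feature_names)
    order = _cluster_order(matrix)
    ordered = frame.iloc[order, order]
    names = [tensor.feature_names[i] for i in order]
    return ordered, {"row_order": names, "col_order": names}


def dependence_data(tensor: InteractionTensor, disease, feature_a: str,
                    feature_b: str, y_true=None,
                    filter: str = "all") -> pd.DataFrame:
    """Per-sample interaction scatter for a feature pair and a disease.

    Columns: value_a, value_b, interaction.  ``filter="class-only"``
    restricts to samples whose ground truth equals the disease.
    """
    if filter not in ("all", "class-only"):
        raise ValueError(f"filter must be 'all' or 'class-only', got {filter!r}")
    j = list(map(str, tensor.classes)).index(str(disease))
    a = tensor.feature_names.index(feature_a)
    b = tensor.feature_names.index(feature_b)
    mask = np.ones(tensor.values.shape[0], dtype=bool)
    if filter == "class-only":
        if y_true is None:
            raise ValueError("class-only filter needs y_true")
        mask = np.asarray(y_true) == tensor.classes[j]
    return pd.DataFrame({
        "value_a": tensor.features[mask, a],
        "value_b": tensor.features[mask, b],
        "interaction": tensor.values[mask, j, a, b],
    })


def waterfall_data(tensor: ShapTensor, sample: int, disease) -> pd.DataFrame:
    """Per-feature contributions for one sample and class, sorted by
    decreasing |attribution|, with the cumulative margin from the base value.

    The last cumulative value equals the ensemble margin for that class.
    """
    j = list(map(str, tensor.classes)).index(str(disease))
    contrib = tensor.values[sample, j, :]
    order = np.argsort(-np.abs(contrib), kind="stable")
    cumulative = tensor.base_values[j] + np.cumsum(contrib[order])
    return pd.DataFrame({
        "feature": [tensor.feature_names[i] for i in order],
        "value": tensor.features[sample, order],
        "attribution": contrib[order],
        "cumulative_margin": cumulative,
    })
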