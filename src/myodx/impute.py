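"""K-nearest-neighbour imputation robust to source-wise missing blocks.

Multi-study cohorts miss whole blocks of muscles: a source that never scored
the lower leg leaves those columns empty for all of its samples.  KNN
imputation handles this well because distances are computed over mutually
observed features only (nan-aware Euclidean, rescaled by coverage) and no
distributional assumption is made.

Disease labels are never part of the imputation feature space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer


class KNNFeatureImputer(BaseEstimator, TransformerMixin):
    """Fill missing cells with the mean of the k nearest training rows.

    Thin, validated wrapper around nan-aware-Euclidean KNN imputation.
    Fit on the training partition only; inside cross-validation a fresh
    imputer is fitted per training fold.

    Parameters
    ----------
    k : int
        Number of neighbour rows averaged per missing cell (default 5).
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y=None) -> "KNNFeatureImputer":
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        self.columns_ = list(X.columns) if isinstance(X, pd.DataFrame) else None
        arr = np.asarray(X, dtype=float)
        never_observed = np.all(np.isnan(arr), axis=0)
        if never_observed.any():
            names = ([self.columns_[i] for i in np.flatnonzero(never_observed)]
                     if self.columns_ else list(np.flatnonzero(never_observed)))
            raise ValueError(
                f"features never observed in training data: {names}"
            )
        self._imputer = KNNImputer(
            n_neighbors=min(self.k, arr.shape[0]), weights="uniform",
            keep_empty_features=False,
        )
        self._imputer.fit(arr)
        return self

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        if np.any(np.all(np.isnan(arr), axis=1)):
            bad = np.flatnonzero(np.all(np.isnan(arr), axis=1))
            raise ValueError(f"rows with no observed feature: {bad.tolist()}")
        out = self._imputer.transform(arr)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def knn_impute(table, k: int = 5):
    """Impute a feature matrix in one shot (fit and transform on itself)."""
    return KNNFeatureImputer(k=k).fit(table).transform(table)
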