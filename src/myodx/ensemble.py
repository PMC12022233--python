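"""Boosted-tree ensemble: margin averaging, softmax, percentile selection.

The classifier is an ensemble of gradient-boosted multiclass models, one per
selected hyperparameter combination.  Prediction averages the members' *raw
margin* outputs (one score per class) and applies the max-subtracted softmax
to the averaged margins; explanations are computed on the same margin scale
so feature attributions stay additive.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

#: fixed booster settings shared by every member
_BASE_PARAMS = {
    "objective": "multi:softprob",
    "tree_method": "hist",
    "verbosity": 0,
    "nthread": 1,
}

#: tunable keys forwarded to xgboost (n_estimators becomes num_boost_round)
_TUNABLE = ("max_depth", "learning_rate", "subsample", "colsample_bytree",
            "min_child_weight", "reg_alpha", "reg_lambda")


def softmax(margins: np.ndarray) -> np.ndarray:
    """Row-wise softmax with row-max subtraction (shift-invariant).

    Accepts a single margin vector or a samples x classes matrix; rows of the
    result are positive and sum to one.
    """
    m = np.asarray(margins, dtype=float)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[None, :]
    if not np.all(np.isfinite(m)):
        raise ValueError("margins must be finite")
    shifted = m - m.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=1, keepdims=True)
    return out[0] if squeeze else out


def select_over_percentile(scores, percentile: float = 90.0) -> list[int]:
    """Indices of trial scores strictly above the given percentile.

    The threshold is the linear-interpolation percentile of the finite
    scores.  If ties leave nothing strictly above it, fall back to the top
    ``max(1, round(n * (1 - percentile/100)))`` scores (stable order), so 60
    trials keep at most 6 members and at least the single best.
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("no finite trial scores to select from")
    idx = np.flatnonzero(finite)
    vals = scores[idx]
    threshold = np.percentile(vals, percentile)
    selected = idx[vals > threshold]
    if selected.size == 0:
        n_top = max(1, round(len(vals) * (100.0 - percentile) / 100.0))
        order = np.argsort(-vals, kind="stable")[:n_top]
        selected = idx[order]
    return sorted(int(i) for i in selected)


class XGBEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of XGBoost multiclass models averaged on raw margins.

    Parameters
    ----------
    member_params : list of dict
        One hyperparameter dict per member (keys: max_depth, learning_rate,
        n_estimators, subsample, colsample_bytree, min_child_weight,
        reg_alpha, reg_lambda).  A single empty dict trains one member with
        xgboost defaults.
    random_state : int
        Seed for tree construction (offset per member).
    """

    def __init__(self, member_params: list[dict] | None = None,
                 random_state: int = 0):
        self.member_params = member_params
        self.random_state = random_state

    def fit(self, X, y) -> "XGBEnsembleClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        codes = np.searchsorted(self.classes_, y)
        dtrain = xgb.DMatrix(X, label=codes)
        self.members_ = []
        params_list = self.member_params or [{}]
        for i, params in enumerate(params_list):
            params = dict(params)
            rounds = int(params.pop("n_estimators", 100))
            booster_params = dict(_BASE_PARAMS)
            booster_params["num_class"] = len(self.classes_)
            booster_params["seed"] = self.random_state + i
            for key in _TUNABLE:
                if key in params:
                    booster_params[key] = params.pop(key)
            if params:
                raise ValueError(f"unknown hyperparameters: {sorted(params)}")
            booster = xgb.train(booster_params, dtrain, num_boost_round=rounds)
            self.members_.append(booster)
        return self

    def _check_X(self, X) -> xgb.DMatrix:
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        return xgb.DMatrix(X)

    def predict_margin(self, X) -> np.ndarray:
        """Mean raw margin matrix (samples x classes) over members."""
        dm = self._check_X(X)
        margins = [b.predict(dm, output_margin=True) for b in self.members_]
        return np.mean(margins, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.predict_margin(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def rank(self, X) -> np.ndarray:
        """Classes per sample sorted by descending probability.

        Ties are broken by fixed class order (position in ``classes_``).
        """
        proba = self.predict_proba(X)
        order = np.argsort(-proba, axis=1, kind="stable")
        return self.classes_[order]

    # -- persistence --------------------------------------------------------

    def save_members(self, directory: str | Path) -> list[str]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, booster in enumerate(self.members_):
            name = f"member_{i:02d}.json"
            booster.save_model(str(directory / name))
            names.append(name)
        (directory / "classes.json").write_text(
            json.dumps([str(c) for c in self.classes_]))
        return names

    @classmethod
    def load_members(cls, directory: str | Path,
                     n_features: int) -> "XGBEnsembleClassifier":
        directory = Path(directory)
        model = cls()
        model.classes_ = np.array(
            json.loads((directory / "classes.json").read_text()))
        model.members_ = []
        for path in sorted(directory.glob("member_*.json")):
            booster = xgb.Booster()
            booster.load_model(str(path))
            model.members_.append(booster)
        if not model.members_:
            raise FileNotFoundError(f"no member models under {directory}")
        model.n_features_in_ = n_features
        return model
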