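"""Class-balancing data augmentation: a modified SMOTE-NC.

Standard SMOTE-NC oversamples minority classes up to the majority count,
interpolating continuous features between same-class neighbours and copying
the majority category among neighbours for nominal features.  Here *every*
class — including the majority — is oversampled to
``ceil(augment_factor * max original class count)``, so the procedure doubles
as a general data augmentation step: interpolated rows no longer sit on the
discrete-scale lattice, blurring the quantization left over after rescaling.

Augmentation is applied to training partitions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator


@dataclass
class AugmentConfig:
    augment_factor: float = 1.0
    k_neighbors: int = 5
    categorical_features: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.augment_factor < 1:
            raise ValueError("augment_factor must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


class SmoteNCAugmenter(BaseEstimator):
    """Oversample all classes to ``ceil(augment_factor * max class count)``.

    Parameters
    ----------
    augment_factor : float
        Target multiplier on the majority-class count; 1.0 balances only.
    k_neighbors : int
        Same-class neighbours considered per seed row (shrinks for classes
        with fewer members).
    categorical_features : list of int
        Column indices treated as nominal: excluded from interpolation
        arithmetic, synthetic value = majority among the neighbour set; they
        contribute the SMOTE-NC constant penalty (median of continuous-feature
        standard deviations) to distances when they differ.
    random_state : int
    """

    def __init__(self, augment_factor: float = 1.0, k_neighbors: int = 5,
                 categorical_features: list[int] | None = None,
                 random_state: int = 0):
        self.augment_factor = augment_factor
        self.k_neighbors = k_neighbors
        self.categorical_features = categorical_features
        self.random_state = random_state

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        config = AugmentConfig(
            augment_factor=self.augment_factor,
            k_neighbors=self.k_neighbors,
            categorical_features=list(self.categorical_features or []),
            seed=self.random_state,
        )
        return smotenc_augment(X, y, config)


def smotenc_augment(X, y, config: AugmentConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(X_aug, y_aug)`` with original rows first, verbatim."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    rng = np.random.default_rng(config.seed)
    cat = np.zeros(X.shape[1], dtype=bool)
    cat[list(config.categorical_features)] = True
    cont = ~cat

    classes, counts = np.unique(y, return_counts=True)
    target = math.ceil(config.augment_factor * counts.max())
    # SMOTE-NC's categorical mismatch penalty: median std of continuous feats
    stds = np.std(X[:, cont], axis=0) if cont.any() else np.array([0.0])
    penalty = float(np.median(stds)) if len(stds) else 0.0

    new_X, new_y = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        n_new = target - len(idx)
        if n_new <= 0:
            continue
        if len(idx) < 2:
            raise ValueError(
                f"class {cls!r} has a single member; cannot interpolate"
            )
        k = min(config.k_neighbors, len(idx) - 1)
        Xc = X[idx]
        # pairwise distances within the class (continuous L2 + cat penalty)
        diff = Xc[:, None, cont] - Xc[None, :, cont]
        d2 = np.sum(diff ** 2, axis=-1)
        if cat.any():
            mismatch = np.sum(Xc[:, None, cat] != Xc[None, :, cat], axis=-1)
            d2 = d2 + mismatch * penalty ** 2
        order = np.argsort(d2, axis=1, kind="stable")  # col 0 = self
        neighbours = order[:, 1:k + 1]

        seeds = rng.integers(0, len(idx), size=n_new)
        picks = rng.integers(0, k, size=n_new)
        gaps = rng.random(size=n_new)
        for s, p, gap in zip(seeds, picks, gaps):
            nb = neighbours[s, p]
            row = Xc[s].copy()
            row[cont] = Xc[s, cont] + gap * (Xc[nb, cont] - Xc[s, cont])
            if cat.any():
                hood = Xc[neighbours[s], :][:, cat]
                for j, col in enumerate(np.flatnonzero(cat)):
                    values, freq = np.unique(hood[:, j], return_counts=True)
                    row[col] = values[np.argmax(freq)]
            new_X.append(row)
            new_y.append(cls)

    if not new_X:
        return X.copy(), y.copy()
    return (np.vstack([X, np.array(new_X)]),
            np.concatenate([y, np.array(new_y, dtype=y.dtype)]))
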