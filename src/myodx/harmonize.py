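"""Harmonization of multi-scale fat scores into the model feature space.

The pipeline turns heterogeneous native scores into features comparable
across studies:

1. align each record to a common muscle list (merge/expand);
2. reduce bilateral scores to per-muscle means, keeping the mean and
   standard deviation of the left/right asymmetry as features;
3. normalize every scale onto 0 (healthy) – 100 (completely fat-replaced);
4. impute missing muscles (K-nearest neighbours, fit on training data);
5. rescale each patient's scores by subtracting the leave-one-out mean,
   turning absolute fat content into within-patient *relative* involvement
   in [−100, 100] — this removes the overall amount of fat replacement
   (disease stage) and with it the systematic offsets that would otherwise
   leak which scale or scorer produced the data;
6. keep the patient's mean involvement (disease stage) as an explicit
   feature, scale age linearly onto [−100, 100], and encode sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortTable, SampleRecord, align_feature_space
from .impute import KNNFeatureImputer
from .taxonomy import DEFAULT_TARGET_MUSCLES

EXTRA_FEATURES = ["mean_involvement", "asymmetry_mean", "asymmetry_sd",
                  "age_scaled", "sex"]
_META = ["sample_id", "patient_id", "disease"]


@dataclass
class HarmonizedTable:
    """Model-ready features: one row per sample.

    ``frame`` columns: sample_id, patient_id, disease, one relative-score
    column per muscle (in [−100, 100]), then mean_involvement,
    asymmetry_mean, asymmetry_sd, age_scaled, sex.
    """

    frame: pd.DataFrame
    muscles: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.muscles) + EXTRA_FEATURES

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["disease"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["patient_id"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.frame[_META + self.feature_names].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "HarmonizedTable":
        frame = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
        muscles = [c for c in frame.columns if c not in _META + EXTRA_FEATURES]
        return cls(frame=frame, muscles=muscles)


# ---------------------------------------------------------------------------
# elementary operations


def reduce_sides(record: SampleRecord) -> tuple[SampleRecord, float, float]:
    """Average bilateral scores; summarize left/right asymmetry.

    Returns ``(mean-score record, asymmetry_mean, asymmetry_sd)``.  Per-muscle
    asymmetry is the absolute left/right difference *after* normalization to
    0–100, so it is comparable across scales; its mean and population
    standard deviation over muscles with both sides summarize the patient.
    Non-bilateral records pass through with NaN asymmetry.
    """
    from dataclasses import replace

    if record.side_mode != "bilateral":
        return record, float("nan"), float("nan")
    scale = record.fat_scale
    means: dict[str, float] = {}
    asyms: list[float] = []
    for muscle, value in record.scores.items():
        if not isinstance(value, tuple):
            raise ValueError(
                f"sample {record.sample_id}: bilateral record has unpaired "
                f"score for {muscle}"
            )
        left, right = value
        means[muscle] = (left + right) / 2.0
        asyms.append(abs(scale.normalize_rank(left) - scale.normalize_rank(right)))
    if asyms:
        a_mean = float(np.mean(asyms))
        a_sd = float(np.std(asyms))  # population (n) denominator
    else:
        a_mean = a_sd = float("nan")
    reduced = replace(record, side_mode="average", scores=dict(means))
    return reduced, a_mean, a_sd


def loo_rescale(scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Leave-one-out rescaling of one patient's normalized scores.

    Each muscle's relative score is its value minus the mean of the patient's
    *other* muscles; the overall mean (before rescaling) is returned as the
    patient's mean involvement.  Requires at least two observed values.
    """
    scores = np.asarray(scores, dtype=float)
    observed = ~np.isnan(scores)
    n = int(observed.sum())
    if n < 2:
        raise ValueError(
            f"leave-one-out rescaling needs >= 2 observed scores, got {n}"
        )
    total = np.nansum(scores)
    loo_mean = (total - scores) / (n - 1)
    relative = np.where(observed, scores - loo_mean, np.nan)
    return relative, float(total / n)


def scale_age(age, age_range: tuple[float, float]) -> np.ndarray:
    """Linear min–max map of age in years onto [−100, 100]; clips outside."""
    lo, hi = age_range
    if not lo < hi:
        raise ValueError(f"degenerate age range [{lo}, {hi}]")
    age = np.asarray(age, dtype=float)
    return np.clip(-100.0 + 200.0 * (age - lo) / (hi - lo), -100.0, 100.0)


def normalized_absolute_scores(
    cohort: CohortTable, target_muscles: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample normalized (0–100) absolute scores plus metadata.

    This is the pipeline state *before* leave-one-out rescaling — the
    representation from which the original scoring scale is still
    recoverable.  Columns: metadata, per-muscle absolute score (NaN when
    missing), asymmetry_mean/sd, age, sex, scale, source_id.
    """
    muscles = list(target_muscles or DEFAULT_TARGET_MUSCLES)
    aligned = align_feature_space(cohort, muscles)
    rows = []
    for rec in aligned.records:
        reduced, a_mean, a_sd = reduce_sides(rec)
        scale = reduced.fat_scale
        row: dict = {
            "sample_id": reduced.sample_id,
            "patient_id": reduced.patient_id,
            "source_id": reduced.source_id,
            "disease": reduced.disease,
            "scale": reduced.scale,
            "age": np.nan if reduced.age is None else reduced.age,
            "sex": {"M": 0.0, "F": 1.0}.get(reduced.sex, np.nan),
            "asymmetry_mean": a_mean,
            "asymmetry_sd": a_sd,
        }
        for m in muscles:
            row[m] = (scale.normalize_rank(reduced.scores[m])
                      if m in reduced.scores else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator


class CohortHarmonizer(BaseEstimator, TransformerMixin):
    """Transform raw cohorts into harmonized model features.

    Stateful pieces — the KNN imputer and the age range — are learned in
    :meth:`fit` from training data only, so test samples never influence
    imputation or age scaling.

    Parameters
    ----------
    target_muscles : list of str, optional
        Common feature space; defaults to the lower-limb set.
    imputer_k : int
        Neighbours for KNN imputation of missing muscles (and of missing
        asymmetry/age/sex in a second pass).
    impute_before_rescale : bool
        When True (default) missing muscles are imputed on the normalized
        absolute scores, so the leave-one-out mean is computed on complete
        vectors; when False, rescaling runs on observed values only and the
        imputer fills relative scores afterwards.
    """

    def __init__(self, target_muscles: list[str] | None = None,
                 imputer_k: int = 5, impute_before_rescale: bool = True):
        self.target_muscles = target_muscles
        self.imputer_k = imputer_k
        self.impute_before_rescale = impute_before_rescale

    def _muscles(self) -> list[str]:
        return list(self.target_muscles or DEFAULT_TARGET_MUSCLES)

    def fit(self, X: CohortTable, y=None) -> "CohortHarmonizer":
        return self._fit_from_absolute(
            normalized_absolute_scores(X, self._muscles()))

    def _fit_from_absolute(self, absolute: pd.DataFrame) -> "CohortHarmonizer":
        muscles = self._muscles()
        ages = absolute["age"].dropna()
        if len(ages) >= 2 and ages.min() < ages.max():
            self.age_range_ = (float(ages.min()), float(ages.max()))
        else:
            self.age_range_ = (0.0, 100.0)  # degenerate cohort fallback
        self.muscle_imputer_ = KNNFeatureImputer(k=self.imputer_k)
        self.muscle_imputer_.fit(absolute[muscles])
        # second pass: asymmetry/age/sex imputed in the harmonized space;
        # features with no observation at all (e.g. asymmetry in a cohort
        # without any bilateral source) are neutralized to 0 instead
        train_features = self._assemble(absolute)
        cols = self._muscles() + EXTRA_FEATURES
        observed = train_features[cols].notna().any(axis=0)
        self.unobserved_features_ = [c for c in cols if not observed[c]]
        imputable = [c for c in cols if observed[c]]
        self.extra_imputer_ = KNNFeatureImputer(k=self.imputer_k)
        self.extra_imputer_.fit(train_features[imputable])
        self.feature_names_ = cols
        return self

    def _assemble(self, absolute: pd.DataFrame) -> pd.DataFrame:
        muscles = self._muscles()
        block = absolute[muscles]
        if self.impute_before_rescale:
            block = self.muscle_imputer_.transform(block)
        relatives = np.empty(block.shape)
        involvement = np.empty(len(block))
        for i, row in enumerate(block.to_numpy(dtype=float)):
            relatives[i], involvement[i] = loo_rescale(row)
        out = absolute[_META].copy()
        out[muscles] = relatives
        if not self.impute_before_rescale:
            out[muscles] = self.muscle_imputer_.transform(out[muscles])
        out["mean_involvement"] = involvement
        out["asymmetry_mean"] = absolute["asymmetry_mean"].to_numpy()
        out["asymmetry_sd"] = absolute["asymmetry_sd"].to_numpy()
        age = absolute["age"].to_numpy(dtype=float)
        scaled = np.full_like(age, np.nan)
        seen = ~np.isnan(age)
        scaled[seen] = scale_age(age[seen], self.age_range_)
        out["age_scaled"] = scaled
        out["sex"] = absolute["sex"].to_numpy()
        return out

    def transform(self, X: CohortTable) -> HarmonizedTable:
        muscles = self._muscles()
        absolute = normalized_absolute_scores(X, muscles)
        frame = self._assemble(absolute)
        cols = muscles + EXTRA_FEATURES
        for c in self.unobserved_features_:
            frame[c] = 0.0
        imputable = [c for c in cols if c not in self.unobserved_features_]
        frame[imputable] = self.extra_imputer_.transform(frame[imputable])
        frame["sex"] = frame["sex"].round().clip(0, 1)
        return HarmonizedTable(frame=frame, muscles=muscles)


def harmonize_cohort(
    cohort: CohortTable, target_muscles: list[str] | None = None,
    imputer_k: int = 5,
) -> HarmonizedTable:
    """One-shot harmonization fitting imputer and age range on the cohort
    itself; inside cross-validation use :class:`CohortHarmonizer` so state is
    learned from training folds only."""
    return (CohortHarmonizer(target_muscles, imputer_k)
            .fit(cohort).transform(cohort))
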