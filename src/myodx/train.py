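"""Nested, patient-grouped cross-validated training with TPE search and
percentile-based ensemble selection.

Protocol: the outer loop splits samples into stratified folds with every
sample of a patient confined to one fold (longitudinal repeats never straddle
a train/test boundary).  Within each outer training partition, an inner
stratified-group loop scores hyperparameter combinations proposed by a
tree-structured Parzen estimator on mean balanced accuracy.  Combinations
scoring strictly above the 90th percentile of the fold's trials are refit on
the full outer training partition and kept as ensemble members.

Harmonization state (imputer, age range), and augmentation are fitted inside
training partitions only — no sample of a test patient influences any fitted
component of its fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .augment import SmoteNCAugmenter
from .cohort import CohortTable
from .ensemble import XGBEnsembleClassifier, select_over_percentile, softmax
from .evaluate import balanced_accuracy
from .harmonize import CohortHarmonizer, HarmonizedTable
from .tpe import Categorical, Integer, Real, SearchSpace, TPESampler, Trial

#: default hyperparameter space (the published search ranges are not public;
#: these are conventional ranges for gradient-boosted trees on small tabular
#: problems, configurable via SearchSpec)
DEFAULT_SPACE: SearchSpace = {
    "max_depth": Integer(2, 10),
    "learning_rate": Real(1e-3, 0.5, log=True),
    "n_estimators": Integer(50, 500),
    "subsample": Real(0.5, 1.0),
    "colsample_bytree": Real(0.5, 1.0),
    "min_child_weight": Real(1.0, 20.0),
    "reg_alpha": Real(1e-8, 10.0, log=True),
    "reg_lambda": Real(1e-8, 10.0, log=True),
}

#: reduced space for desk-scale runs (shallower, fewer trees)
FAST_SPACE: SearchSpace = {
    "max_depth": Integer(2, 6),
    "learning_rate": Real(0.01, 0.5, log=True),
    "n_estimators": Integer(50, 200),
    "subsample": Real(0.5, 1.0),
    "colsample_bytree": Real(0.5, 1.0),
    "min_child_weight": Real(1.0, 20.0),
    "reg_alpha": Real(1e-8, 10.0, log=True),
    "reg_lambda": Real(1e-8, 10.0, log=True),
}


@dataclass
class SearchSpec:
    space: SearchSpace = field(default_factory=lambda: dict(DEFAULT_SPACE))
    n_startup: int = 30
    n_trials: int = 60
    percentile: float = 90.0
    outer_folds: int = 10
    inner_folds: int = 5
    augment_factor: float = 1.0
    imputer_k: int = 5
    target_muscles: list[str] | None = None
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0) -> "SearchSpec":
        """Desk-scale protocol: 5x3 folds, 10 trials, reduced space."""
        return cls(space=dict(FAST_SPACE), n_startup=5, n_trials=10,
                   outer_folds=5, inner_folds=3, seed=seed)


@dataclass
class FoldResult:
    fold: int
    test_index: np.ndarray
    model: XGBEnsembleClassifier
    harmonizer: CohortHarmonizer
    trials: list[Trial]
    selected: list[int]
    probabilities: np.ndarray  # test samples x classes
    balanced_accuracy: float


@dataclass
class NestedCVResult:
    folds: list[FoldResult]
    classes: np.ndarray
    oof_proba: np.ndarray  # all samples x classes, pooled out-of-fold
    y: np.ndarray
    sample_ids: np.ndarray
    feature_names: list[str]

    @property
    def fold_scores(self) -> list[float]:
        return [f.balanced_accuracy for f in self.folds]


def _seeds(root: int, n: int, salt: int = 0) -> list[int]:
    """Deterministic child seeds below 2**31 from one root seed."""
    ss = np.random.SeedSequence([root, salt])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _cohort_subset(cohort: CohortTable, index: np.ndarray) -> CohortTable:
    return CohortTable(records=[cohort.records[i] for i in index],
                       taxonomy=cohort.taxonomy)


def _augmented_arrays(table: HarmonizedTable, augment_factor: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    sex_col = table.feature_names.index("sex")
    augmenter = SmoteNCAugmenter(augment_factor=augment_factor,
                                 categorical_features=[sex_col],
                                 random_state=seed)
    return augmenter.fit_resample(table.X, table.y)


def _fit_fold_model(params_list: list[dict], table: HarmonizedTable,
                    augment_factor: float, seed: int) -> XGBEnsembleClassifier:
    Xa, ya = _augmented_arrays(table, augment_factor, seed)
    model = XGBEnsembleClassifier(member_params=params_list, random_state=seed)
    return model.fit(Xa, ya)


def tpe_search(cohort_train: CohortTable, spec: SearchSpec,
               seed: int) -> list[Trial]:
    """Score ``spec.n_trials`` TPE-proposed combinations by mean balanced
    accuracy over the inner stratified-group folds.

    Harmonization (imputer, age range) is fitted per inner training fold;
    the resulting datasets are cached and reused across trials.  Trials with
    a non-finite objective are kept in the log with a NaN score and excluded
    from percentile selection.
    """
    y = np.array([r.disease for r in cohort_train.records])
    groups = np.array([r.patient_id for r in cohort_train.records])
    inner = StratifiedGroupKFold(n_splits=spec.inner_folds, shuffle=True,
                                 random_state=seed % (2 ** 31))
    fold_seeds = _seeds(seed, spec.inner_folds, salt=1)
    datasets = []
    for k, (tr, va) in enumerate(inner.split(np.zeros(len(y)), y, groups)):
        harmonizer = CohortHarmonizer(target_muscles=spec.target_muscles,
                                      imputer_k=spec.imputer_k)
        harmonizer.fit(_cohort_subset(cohort_train, tr))
        t_train = harmonizer.transform(_cohort_subset(cohort_train, tr))
        t_val = harmonizer.transform(_cohort_subset(cohort_train, va))
        Xa, ya = _augmented_arrays(t_train, spec.augment_factor, fold_seeds[k])
        datasets.append((Xa, ya, t_val.X, t_val.y))

    sampler = TPESampler(spec.space, seed=seed, n_startup=spec.n_startup)
    member_seeds = _seeds(seed, spec.n_trials, salt=2)
    for t in range(spec.n_trials):
        params = sampler.ask()
        scores = []
        try:
            for Xa, ya, Xv, yv in datasets:
                model = XGBEnsembleClassifier(member_params=[params],
                                              random_state=member_seeds[t])
                model.fit(Xa, ya)
                scores.append(balanced_accuracy(yv, model.predict(Xv)))
            objective = float(np.mean(scores))
        except Exception:
            objective = float("nan")
        sampler.tell(params, objective)
    return sampler.trials


def build_ensemble(trials: list[Trial], table_train: HarmonizedTable,
                   percentile: float = 90.0, augment_factor: float = 1.0,
                   seed: int = 0) -> tuple[XGBEnsembleClassifier, list[int]]:
    """Refit the trials scoring strictly above the percentile on the full
    training partition and bundle them as ensemble members."""
    scores = [t.score for t in trials]
    selected = select_over_percentile(scores, percentile)
    params_list = [trials[i].params for i in selected]
    model = _fit_fold_model(params_list, table_train, augment_factor, seed)
    return model, selected


def nested_cv(cohort: CohortTable, spec: SearchSpec | None = None,
              verbose: bool = False) -> NestedCVResult:
    """Run the full nested cross-validation on a raw cohort."""
    spec = spec or SearchSpec()
    y = np.array([r.disease for r in cohort.records])
    groups = np.array([r.patient_id for r in cohort.records])
    sample_ids = np.array([r.sample_id for r in cohort.records])
    classes = np.unique(y)
    outer = StratifiedGroupKFold(n_splits=spec.outer_folds, shuffle=True,
                                 random_state=spec.seed % (2 ** 31))
    fold_seeds = _seeds(spec.seed, spec.outer_folds, salt=10)
    oof = np.full((len(y), len(classes)), np.nan)
    folds: list[FoldResult] = []
    feature_names: list[str] = []
    for k, (tr, te) in enumerate(outer.split(np.zeros(len(y)), y, groups)):
        cohort_train = _cohort_subset(cohort, tr)
        trials = tpe_search(cohort_train, spec, fold_seeds[k])
        harmonizer = CohortHarmonizer(target_muscles=spec.target_muscles,
                                      imputer_k=spec.imputer_k)
        harmonizer.fit(cohort_train)
        t_train = harmonizer.transform(cohort_train)
        t_test = harmonizer.transform(_cohort_subset(cohort, te))
        feature_names = t_train.feature_names
        selected = select_over_percentile([t.score for t in trials],
                                          spec.percentile)
        model = _fit_fold_model([trials[i].params for i in selected],
                                t_train, spec.augment_factor, fold_seeds[k])
        proba = model.predict_proba(t_test.X)
        # align member class order with the global class order
        col = np.searchsorted(classes, model.classes_)
        proba_full = np.zeros((len(te), len(classes)))
        proba_full[:, col] = proba
        oof[te] = proba_full
        ba = balanced_accuracy(t_test.y,
                               classes[np.argmax(proba_full, axis=1)])
        if verbose:
            print(f"fold {k}: {len(selected)} members, "
                  f"balanced accuracy {ba:.3f}")
        folds.append(FoldResult(
            fold=k, test_index=te, model=model, harmonizer=harmonizer,
            trials=trials, selected=selected, probabilities=proba_full,
            balanced_accuracy=ba,
        ))
    return NestedCVResult(folds=folds, classes=classes, oof_proba=oof, y=y,
                          sample_ids=sample_ids, feature_names=feature_names)


# ---------------------------------------------------------------------------
# baselines

_RF_SPACE: SearchSpace = {
    "n_estimators": Integer(100, 500),
    "max_depth": Integer(3, 20),
    "max_features": Real(0.2, 1.0),
    "min_samples_leaf": Integer(1, 10),
}
_KNN_SPACE: SearchSpace = {
    "n_neighbors": Integer(1, 25),
    "weights": Categorical(["uniform", "distance"]),
}


def _baseline_model(algorithm: str, params: dict, seed: int):
    if algorithm == "random-forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "k-nearest-neighbour":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown baseline algorithm {algorithm!r}")


def train_baseline(cohort: CohortTable, algorithm: str,
                   spec: SearchSpec | None = None) -> dict:
    """Fit a baseline classifier under the identical nested protocol
    (same folds, same inner scoring, same augmentation) for paired
    comparison with the boosted ensemble.

    Baseline probabilities are used directly (no margin averaging); the
    inner search picks the single best combination per fold.
    """
    spec = spec or SearchSpec()
    space = _RF_SPACE if algorithm == "random-forest" else _KNN_SPACE
    y = np.array([r.disease for r in cohort.records])
    groups = np.array([r.patient_id for r in cohort.records])
    classes = np.unique(y)
    outer = StratifiedGroupKFold(n_splits=spec.outer_folds, shuffle=True,
                                 random_state=spec.seed % (2 ** 31))
    fold_seeds = _seeds(spec.seed, spec.outer_folds, salt=10)
    oof = np.full((len(y), len(classes)), np.nan)
    fold_scores = []
    for k, (tr, te) in enumerate(outer.split(np.zeros(len(y)), y, groups)):
        cohort_train = _cohort_subset(cohort, tr)
        seed = fold_seeds[k]
        inner = StratifiedGroupKFold(n_splits=spec.inner_folds, shuffle=True,
                                     random_state=seed % (2 ** 31))
        y_tr = y[tr]
        g_tr = groups[tr]
        inner_sets = []
        inner_seeds = _seeds(seed, spec.inner_folds, salt=1)
        for j, (itr, iva) in enumerate(
                inner.split(np.zeros(len(tr)), y_tr, g_tr)):
            h = CohortHarmonizer(target_muscles=spec.target_muscles,
                                 imputer_k=spec.imputer_k)
            h.fit(_cohort_subset(cohort_train, itr))
            t_train = h.transform(_cohort_subset(cohort_train, itr))
            t_val = h.transform(_cohort_subset(cohort_train, iva))
            Xa, ya = _augmented_arrays(t_train, spec.augment_factor,
                                       inner_seeds[j])
            inner_sets.append((Xa, ya, t_val.X, t_val.y))
        sampler = TPESampler(space, seed=seed, n_startup=spec.n_startup)
        for _ in range(spec.n_trials):
            params = sampler.ask()
            try:
                scores = []
                for Xa, ya, Xv, yv in inner_sets:
                    model = _baseline_model(algorithm, params, seed)
                    model.fit(Xa, ya)
                    scores.append(balanced_accuracy(yv, model.predict(Xv)))
                sampler.tell(params, float(np.mean(scores)))
            except Exception:
                sampler.tell(params, float("nan"))
        ok = [t for t in sampler.trials if t.ok]
        best = max(ok, key=lambda t: t.score)
        h = CohortHarmonizer(target_muscles=spec.target_muscles,
                             imputer_k=spec.imputer_k)
        h.fit(cohort_train)
        t_train = h.transform(cohort_train)
        t_test = h.transform(_cohort_subset(cohort, te))
        Xa, ya = _augmented_arrays(t_train, spec.augment_factor, seed)
        model = _baseline_model(algorithm, best.params, seed)
        model.fit(Xa, ya)
        proba = model.predict_proba(t_test.X)
        col = np.searchsorted(classes, model.classes_)
        proba_full = np.zeros((len(te), len(classes)))
        proba_full[:, col] = proba
        oof[te] = proba_full
        fold_scores.append(balanced_accuracy(
            t_test.y, classes[np.argmax(proba_full, axis=1)]))
    return {"algorithm": algorithm, "classes": classes, "oof_proba": oof,
            "y": y, "fold_scores": fold_scores,
            "balanced_accuracy": float(np.mean(fold_scores))}


# ---------------------------------------------------------------------------
# deployment bundle


def save_bundle(result: NestedCVResult, cohort: CohortTable,
                spec: SearchSpec, directory: str | Path,
                pool_folds: bool = True) -> Path:
    """Persist a deployment model: members refit on the full cohort using the
    hyperparameters selected across folds (pooled) or of the first fold."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params_list = []
    for f in (result.folds if pool_folds else result.folds[:1]):
        params_list.extend(f.trials[i].params for i in f.selected)
    harmonizer = CohortHarmonizer(target_muscles=spec.target_muscles,
                                  imputer_k=spec.imputer_k)
    harmonizer.fit(cohort)
    table = harmonizer.transform(cohort)
    model = _fit_fold_model(params_list, table, spec.augment_factor, spec.seed)
    model.save_members(directory)
    # persist harmonizer state: the normalized absolute training scores
    from .harmonize import normalized_absolute_scores
    absolute = normalized_absolute_scores(cohort, harmonizer._muscles())
    absolute.to_csv(directory / "harmonizer_train.csv", index=False)
    manifest = {
        "classes": [str(c) for c in model.classes_],
        "feature_names": table.feature_names,
        "target_muscles": harmonizer._muscles(),
        "age_range": list(harmonizer.age_range_),
        "imputer_k": spec.imputer_k,
        "augment_factor": spec.augment_factor,
        "seed": spec.seed,
        "pool_folds": pool_folds,
        "selection_scores": {
            str(f.fold): [f.trials[i].score for i in f.selected]
            for f in result.folds
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_bundle(directory: str | Path):
    """Load a deployment bundle -> (model, harmonizer, manifest)."""
    import pandas as pd

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    model = XGBEnsembleClassifier.load_members(
        directory, n_features=len(manifest["feature_names"]))
    harmonizer = CohortHarmonizer(
        target_muscles=manifest["target_muscles"],
        imputer_k=manifest["imputer_k"])
    absolute = pd.read_csv(directory / "harmonizer_train.csv",
                           dtype={"sample_id": str, "patient_id": str})
    harmonizer._fit_from_absolute(absolute)
    harmonizer.age_range_ = tuple(manifest["age_range"])
    return model, harmonizer, manifest
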