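"""Cohort data structures and the merge/expand algebra.

A :class:`SampleRecord` is one MRI study of one patient: metadata plus a
mapping of muscle (or muscle-group) name to fat score.  Discrete scores are
held internally in *rank space* — the 0-based ordinal rank of the level,
which may be fractional after averaging — and continuous fat fractions are
held as-is.  Rank space makes averaging well defined for scales with
non-numeric levels such as 2a/2b.

Patients may repeat across records (longitudinal follow-up); each time point
is a separate sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .scales import SCALES, FatScale, get_scale
from .taxonomy import MuscleTaxonomy, default_taxonomy

SIDE_MODES = ("bilateral", "average", "unilateral")

#: score value: float (rank space / FF) or an (L, R) pair for bilateral records
Score = float | tuple[float, float]


@dataclass
class SampleRecord:
    sample_id: str
    patient_id: str
    source_id: str
    disease: str
    age: float | None
    sex: str | None  # "M" | "F" | None
    side_mode: str
    scale: str
    scores: dict[str, Score] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side_mode not in SIDE_MODES:
            raise ValueError(
                f"sample {self.sample_id}: side_mode {self.side_mode!r} "
                f"not one of {SIDE_MODES}"
            )
        if self.sex not in ("M", "F", None):
            raise ValueError(f"sample {self.sample_id}: sex {self.sex!r}")

    @property
    def fat_scale(self) -> FatScale:
        return get_scale(self.scale)

    def score_values(self, name: str) -> tuple[float, ...]:
        """The score(s) for a muscle as a flat tuple (1 or 2 values)."""
        v = self.scores[name]
        return tuple(v) if isinstance(v, tuple) else (v,)

    def validate(self) -> list[str]:
        """Range/shape problems with this record (empty list = valid)."""
        problems = []
        scale = self.fat_scale
        lo, hi = (0.0, 100.0) if scale.kind == "continuous" else (0.0, scale.n_levels - 1.0)
        for muscle, value in self.scores.items():
            values = (value,) if not isinstance(value, tuple) else value
            if self.side_mode == "bilateral" and len(values) != 2:
                problems.append(f"{muscle}: bilateral record needs (L, R) pair")
            if self.side_mode != "bilateral" and len(values) != 1:
                problems.append(f"{muscle}: non-bilateral record needs one value")
            for v in values:
                if not math.isnan(v) and not lo <= v <= hi:
                    problems.append(
                        f"{muscle}: score {v} outside native range of scale "
                        f"{self.scale!r}"
                    )
        return problems


@dataclass
class CohortTable:
    records: list[SampleRecord]
    taxonomy: MuscleTaxonomy = field(default_factory=default_taxonomy)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.scale not in SCALES:
                raise ValueError(
                    f"sample {rec.sample_id}: unknown scale {rec.scale!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> dict[str, list[str]]:
        """Per-sample validation report; raises nothing, empty dict = clean."""
        report = {}
        known = self.taxonomy.names
        for rec in self.records:
            problems = rec.validate()
            for muscle in rec.scores:
                if muscle not in known:
                    problems.append(f"{muscle}: not in taxonomy")
            if problems:
                report[rec.sample_id] = problems
        return report

    def require_valid(self) -> None:
        report = self.validate()
        if report:
            lines = [f"  {sid}: {'; '.join(p)}" for sid, p in report.items()]
            raise ValueError("invalid cohort:\n" + "\n".join(lines))


# ---------------------------------------------------------------------------
# merge / expand algebra


def _mean_scores(values: list[Score]) -> Score:
    """Mean of member scores, per side when bilateral pairs are given."""
    if isinstance(values[0], tuple):
        left = float(np.mean([v[0] for v in values]))
        right = float(np.mean([v[1] for v in values]))
        return (left, right)
    return float(np.mean(values))


def merge_muscles(
    record: SampleRecord, group: str, taxonomy: MuscleTaxonomy | None = None
) -> SampleRecord:
    """Replace a group's member columns by one group column holding their mean.

    All members must be present (per side when bilateral); merging with a
    missing member is refused so group scores are never silently biased.
    """
    taxonomy = taxonomy or default_taxonomy()
    members = taxonomy.members(group)
    absent = sorted(m for m in members if m not in record.scores)
    if absent:
        raise KeyError(
            f"sample {record.sample_id}: cannot merge {group!r}; "
            f"missing members {absent}"
        )
    scores = {k: v for k, v in record.scores.items() if k not in members}
    scores[group] = _mean_scores([record.scores[m] for m in sorted(members)])
    return replace(record, scores=scores)


def expand_group(
    record: SampleRecord, group: str, taxonomy: MuscleTaxonomy | None = None
) -> SampleRecord:
    """Replace a group column by one column per member copying the group score."""
    taxonomy = taxonomy or default_taxonomy()
    members = taxonomy.members(group)
    if group not in record.scores:
        raise KeyError(f"sample {record.sample_id}: group {group!r} not present")
    scores = {k: v for k, v in record.scores.items() if k != group}
    value = record.scores[group]
    for m in sorted(members):
        scores[m] = value
    return replace(record, scores=scores)


def _target_value(
    record: SampleRecord, target: str, taxonomy: MuscleTaxonomy
) -> Score | None:
    """Value of ``target`` reachable from ``record`` via merge/expand, else None."""
    if target in record.scores:
        return record.scores[target]
    if target in taxonomy.groups:
        # merge: every member must be obtainable, else missing
        member_values = []
        for m in sorted(taxonomy.members(target)):
            v = _target_value(record, m, taxonomy)
            if v is None:
                return None
            member_values.append(v)
        return _mean_scores(member_values)
    # expand: an enclosing group carries the value
    enclosing = taxonomy.group_of(target)
    if enclosing is not None and enclosing in record.scores:
        return record.scores[enclosing]
    return None


def align_feature_space(
    cohort: CohortTable, target_muscles: Iterable[str]
) -> CohortTable:
    """Project every record onto exactly the target columns via merge/expand.

    Targets unreachable from a record become missing; observed values are
    never altered, and no non-missing value is invented.
    """
    targets = list(target_muscles)
    for t in targets:
        cohort.taxonomy.validate_name(t)
    aligned = []
    for rec in cohort.records:
        scores: dict[str, Score] = {}
        for t in targets:
            v = _target_value(rec, t, cohort.taxonomy)
            if v is not None:
                scores[t] = v
        aligned.append(replace(rec, scores=scores))
    return CohortTable(records=aligned, taxonomy=cohort.taxonomy)


# ---------------------------------------------------------------------------
# CSV I/O
#
# One row per sample; metadata columns then `<muscle>` or `<muscle>_left` /
# `<muscle>_right`.  Discrete levels are accepted as labels ("2a") or
# numerics on the native axis; missing = empty cell.

_META_COLS = ["sample_id", "patient_id", "source_id", "disease",
              "age", "sex", "side_mode", "scale"]


def _parse_native(raw, scale: FatScale) -> float:
    """Native CSV cell -> rank space (discrete) or FF value (continuous)."""
    if scale.kind == "continuous":
        return float(raw)
    text = str(raw).strip()
    try:
        return float(scale.rank(text))
    except ValueError:
        pass
    # numeric on the native axis (e.g. 1.5 on the 0-4 scale)
    value = float(text)
    if not all(_is_number(lv) for lv in scale.levels):
        raise ValueError(
            f"scale {scale.id!r} has non-numeric levels; score {raw!r} "
            "must be a level label"
        )
    lo = float(scale.levels[0])
    rank = value - lo
    if not 0.0 <= rank <= scale.n_levels - 1:
        raise ValueError(f"score {raw!r} outside native range of {scale.id!r}")
    return rank


def _format_native(rank: float, scale: FatScale) -> str:
    if scale.kind == "continuous":
        return f"{rank:g}"
    if float(rank).is_integer():
        return scale.levels[int(rank)]
    if all(_is_number(lv) for lv in scale.levels):
        return f"{float(scale.levels[0]) + rank:g}"
    raise ValueError(
        f"cannot write fractional rank {rank} on labelled scale {scale.id!r}"
    )


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def read_cohort_csv(
    path: str | Path, taxonomy: MuscleTaxonomy | None = None
) -> CohortTable:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str,
                                  "source_id": str}, keep_default_na=True)
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"cohort CSV lacks metadata columns {missing_meta}")
    score_cols = [c for c in df.columns if c not in _META_COLS]
    records = []
    for _, row in df.iterrows():
        scale = get_scale(str(row["scale"]))
        side_mode = str(row["side_mode"])
        scores: dict[str, Score] = {}
        for col in score_cols:
            if pd.isna(row[col]):
                continue
            value = _parse_native(row[col], scale)
            if col.endswith("_left") or col.endswith("_right"):
                muscle, side = col.rsplit("_", 1)
                pair = scores.get(muscle, (math.nan, math.nan))
                if not isinstance(pair, tuple):
                    raise ValueError(f"{muscle}: mixed sided/unsided columns")
                scores[muscle] = (value, pair[1]) if side == "left" else (pair[0], value)
            else:
                scores[col] = value
        if side_mode == "bilateral":
            # keep only muscles with both sides observed
            scores = {m: v for m, v in scores.items()
                      if isinstance(v, tuple) and not any(map(math.isnan, v))}
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            source_id=str(row["source_id"]),
            disease=str(row["disease"]),
            age=None if pd.isna(row["age"]) else float(row["age"]),
            sex=None if pd.isna(row["sex"]) else str(row["sex"]),
            side_mode=side_mode,
            scale=scale.id,
            scores=scores,
        ))
    return CohortTable(records=records, taxonomy=taxonomy or default_taxonomy())


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    muscles = sorted({m for rec in cohort.records for m in rec.scores})
    rows = []
    for rec in cohort.records:
        scale = rec.fat_scale
        row = {
            "sample_id": rec.sample_id, "patient_id": rec.patient_id,
            "source_id": rec.source_id, "disease": rec.disease,
            "age": rec.age, "sex": rec.sex,
            "side_mode": rec.side_mode, "scale": rec.scale,
        }
        for m, v in rec.scores.items():
            if isinstance(v, tuple):
                row[f"{m}_left"] = _format_native(v[0], scale)
                row[f"{m}_right"] = _format_native(v[1], scale)
            else:
                row[m] = _format_native(v, scale)
        rows.append(row)
    cols = _META_COLS + [c for m in muscles
                         for c in (m, f"{m}_left", f"{m}_right")]
    df = pd.DataFrame(rows)
    ordered = [c for c in cols if c in df.columns]
    df[ordered].to_csv(path, index=False)
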