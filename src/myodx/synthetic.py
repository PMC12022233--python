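"""Synthetic multi-study cohorts with the structure the pipeline assumes.

Each disease is a *prototype*: per-muscle relative severity weights in
[0, 1].  A patient draws a disease stage ``s ~ Beta(a, b)``; the continuous
fat fraction of muscle ``m`` is ``clip(100 * s * prototype_m + noise, 0,
100)``, with left/right sides split by Gaussian asymmetry noise.  The
patient is then observed through a *source*: a study with one scoring scale,
one side-reporting mode, a fixed subset of observed muscles (block
missingness), and an optional systematic scoring offset (operator/protocol
bias).  Discrete scales quantize the fat fraction into equal-width bins.
Longitudinal repeats advance the stage by the disease's progression rate.

Two cohort designs ship as defaults:

* :func:`default_specs` — eight diseases spread evenly over five sources
  (one per scale), for end-to-end pipeline recovery;
* :func:`confounded_specs` — each disease bound to a single source, so the
  scoring scale is confounded with the diagnosis; used to demonstrate scale
  information leakage and its removal by harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, SampleRecord
from .scales import get_scale
from .taxonomy import DEFAULT_TARGET_MUSCLES, default_taxonomy


@dataclass(frozen=True)
class DiseaseSpec:
    name: str
    prototype: dict[str, float]
    n_patients: int = 50
    progression_rate: float = 0.12  # stage increase per follow-up interval
    age_mean: float = 40.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (5.0, 85.0)
    sex_ratio_f: float = 0.5
    repeat_prob: float = 0.15
    asymmetry_sd: float | None = None  # override of cohort-level default

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError(f"{self.name}: need >= 2 patients")
        if not any(w > 0 for w in self.prototype.values()):
            raise ValueError(f"{self.name}: prototype has no positive weight")

    @property
    def top_muscles(self) -> list[str]:
        """The five most involved muscles — the planted discriminative set."""
        return sorted(self.prototype, key=lambda m: (-self.prototype[m], m))[:5]


@dataclass(frozen=True)
class SourceSpec:
    name: str
    scale: str
    side_mode: str
    observed_muscles: tuple[str, ...]
    offset: float = 0.0  # systematic scoring bias, normalized 0-100 units
    disease_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.observed_muscles:
            raise ValueError(f"source {self.name}: observes no muscles")
        get_scale(self.scale)


@dataclass
class CohortSpec:
    diseases: list[DiseaseSpec]
    sources: list[SourceSpec]
    noise_sd: float = 8.0
    asymmetry_sd: float = 5.0
    stage_alpha: float = 2.0
    stage_beta: float = 2.0

    def __post_init__(self) -> None:
        names = [d.name for d in self.diseases]
        if len(set(names)) != len(names):
            raise ValueError("duplicate disease names")
        muscles = set(DEFAULT_TARGET_MUSCLES)
        for src in self.sources:
            unknown = set(src.observed_muscles) - muscles
            if unknown:
                raise ValueError(
                    f"source {src.name}: unknown muscles {sorted(unknown)}")
        for dis in self.diseases:
            if not self._sources_for(dis.name):
                raise ValueError(f"disease {dis.name}: no eligible source")

    def _sources_for(self, disease: str) -> list[tuple[SourceSpec, float]]:
        out = []
        for src in self.sources:
            w = (1.0 if src.disease_weights is None
                 else src.disease_weights.get(disease, 0.0))
            if w > 0:
                out.append((src, w))
        return out


def generate_cohort(spec: CohortSpec, seed: int) -> tuple[CohortTable, dict]:
    """Generate a cohort plus a ground-truth record for recovery tests."""
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    truth_patients: dict[str, dict] = {}
    sample_no = 0
    for dis in spec.diseases:
        eligible = spec._sources_for(dis.name)
        weights = np.array([w for _, w in eligible], dtype=float)
        weights /= weights.sum()
        asym_sd = dis.asymmetry_sd if dis.asymmetry_sd is not None else spec.asymmetry_sd
        for p in range(dis.n_patients):
            pid = f"{dis.name}_p{p:03d}"
            stage = float(rng.beta(spec.stage_alpha, spec.stage_beta))
            age = float(np.clip(rng.normal(dis.age_mean, dis.age_sd),
                                *dis.age_bounds))
            sex = "F" if rng.random() < dis.sex_ratio_f else "M"
            source = eligible[rng.choice(len(eligible), p=weights)][0]
            stages = [stage]
            if rng.random() < dis.repeat_prob:
                stages.append(min(1.0, stage + dis.progression_rate
                                  * rng.uniform(0.5, 1.5)))
            for t, s in enumerate(stages):
                rec = _observe(rng, spec, dis, source, s, pid, age + t,
                               sex, sample_no, asym_sd)
                records.append(rec)
                sample_no += 1
            truth_patients[pid] = {
                "disease": dis.name, "stages": stages,
                "source": source.name, "scale": source.scale,
                "age": age, "sex": sex,
            }
    truth = {
        "patients": truth_patients,
        "prototypes": {d.name: dict(d.prototype) for d in spec.diseases},
        "top_muscles": {d.name: d.top_muscles for d in spec.diseases},
        "sources": {s.name: {"scale": s.scale, "side_mode": s.side_mode,
                             "offset": s.offset,
                             "observed": list(s.observed_muscles)}
                    for s in spec.sources},
        "seed": seed,
    }
    return CohortTable(records=records, taxonomy=default_taxonomy()), truth


def _observe(rng, spec: CohortSpec, dis: DiseaseSpec, src: SourceSpec,
             stage: float, pid: str, age: float, sex: str,
             sample_no: int, asym_sd: float) -> SampleRecord:
    scale = get_scale(src.scale)
    scores = {}
    for m in src.observed_muscles:
        w = dis.prototype.get(m, 0.0)
        ff = 100.0 * stage * w + rng.normal(0.0, spec.noise_sd) + src.offset
        asym = rng.normal(0.0, asym_sd)
        left = float(np.clip(ff + asym / 2.0, 0.0, 100.0))
        right = float(np.clip(ff - asym / 2.0, 0.0, 100.0))
        if src.side_mode == "bilateral":
            scores[m] = (_to_rank(left, scale), _to_rank(right, scale))
        elif src.side_mode == "average":
            scores[m] = _to_rank((left + right) / 2.0, scale)
        else:  # unilateral
            scores[m] = _to_rank(left, scale)
    return SampleRecord(
        sample_id=f"s{sample_no:05d}", patient_id=pid, source_id=src.name,
        disease=dis.name, age=age, sex=sex, side_mode=src.side_mode,
        scale=src.scale, scores=scores,
    )


def _to_rank(ff: float, scale) -> float:
    """Quantize a fat fraction to the scale and return it in rank space."""
    level = scale.quantize(ff)
    return float(level) if scale.kind == "continuous" else float(scale.rank(level))


def inject_missing_blocks(cohort: CohortTable,
                          masks: dict[str, list[str]]) -> CohortTable:
    """Remove the masked muscles from every sample of each source.

    ``masks`` maps source_id -> muscles to blank out.  A mask that would
    leave a sample with no scores at all is refused.
    """
    from dataclasses import replace

    records = []
    for rec in cohort.records:
        mask = set(masks.get(rec.source_id, ()))
        scores = {m: v for m, v in rec.scores.items() if m not in mask}
        if rec.scores and not scores:
            raise ValueError(
                f"mask for source {rec.source_id!r} removes every muscle of "
                f"sample {rec.sample_id}"
            )
        records.append(replace(rec, scores=scores))
    return CohortTable(records=records, taxonomy=cohort.taxonomy)


# ---------------------------------------------------------------------------
# default designs

_BG = 0.08  # background involvement weight for unlisted muscles


def _proto(**named: float) -> dict[str, float]:
    proto = {m: _BG for m in DEFAULT_TARGET_MUSCLES}
    proto.update(named)
    return proto


#: Eight planted disease patterns (invented, loosely modelled on the
#: selectivity families seen in limb-girdle and distal myopathies).
_DISEASE_PROTOS: dict[str, dict[str, float]] = {
    "pelvifemoral": _proto(
        gluteus_maximus=0.95, adductor_magnus=0.90, gluteus_medius=0.85,
        adductor_longus=0.80, pectineus=0.75, gluteus_minimus=0.40,
        quadratus_femoris=0.35),
    "posterior_thigh": _proto(
        semimembranosus=0.95, bflh=0.90, semitendinosus=0.85,
        adductor_magnus=0.80, bfsh=0.75, gracilis=0.30),
    "quadriceps_pattern": _proto(
        vastus_lateralis=0.95, vastus_intermedius=0.90, vastus_medialis=0.85,
        rectus_femoris=0.80, sartorius=0.70),
    "anterior_distal": _proto(
        tibialis_anterior=0.95, extensors=0.90, fhl=0.75, peronei=0.70,
        fdl=0.65),
    "posterior_distal": _proto(
        soleus=0.95, gastrocnemius_medialis=0.90,
        gastrocnemius_lateralis=0.85, tibialis_posterior=0.80, fdl=0.70),
    "flexor_pattern": _proto(
        iliopsoas=0.95, gracilis=0.90, sartorius=0.85, rectus_femoris=0.75,
        pectineus=0.65),
    "scapuloperoneal": _proto(
        peronei=0.95, tibialis_anterior=0.90, gluteus_medius=0.80,
        extensors=0.75, gastrocnemius_lateralis=0.60),
    "posterior_pelvic": _proto(
        piriformis=0.95, obturator_internus=0.90, obturator_externus=0.85,
        quadratus_femoris=0.80, gluteus_minimus=0.75),
}

_AGE_MEANS = {"pelvifemoral": 25, "posterior_thigh": 45,
              "quadriceps_pattern": 55, "anterior_distal": 35,
              "posterior_distal": 50, "flexor_pattern": 30,
              "scapuloperoneal": 40, "posterior_pelvic": 60}

#: upper-pelvis and lower-leg blocks used as source-wise missing patterns
_UPPER_PELVIS = ("piriformis", "obturator_externus", "obturator_internus",
                 "pectineus", "quadratus_femoris")
_LOWER_LEG = ("tibialis_anterior", "tibialis_posterior", "peronei",
              "gastrocnemius_medialis", "gastrocnemius_lateralis", "soleus",
              "fhl", "fdl", "extensors")


def _observed(exclude: tuple[str, ...] = ()) -> tuple[str, ...]:
    return tuple(m for m in DEFAULT_TARGET_MUSCLES if m not in exclude)


def default_specs(n_patients: int = 50,
                  class_imbalance: bool = True) -> CohortSpec:
    """Eight diseases over five sources (one per scale), mixed assignment.

    ``n_patients`` is the per-disease baseline; with ``class_imbalance`` two
    diseases are doubled and two halved, mimicking the skewed class counts
    of pooled real cohorts.  The scapuloperoneal pattern carries raised
    asymmetry noise to exercise the asymmetry features.
    """
    sizes = {d: n_patients for d in _DISEASE_PROTOS}
    if class_imbalance:
        # 4:1 imbalance; totals 8 * n_patients over the eight diseases
        sizes["posterior_thigh"] = n_patients * 2
        sizes["pelvifemoral"] = n_patients * 2
        sizes["flexor_pattern"] = max(4, n_patients // 2)
        sizes["posterior_pelvic"] = max(4, n_patients // 2)
        sizes["posterior_distal"] = max(4, n_patients // 2)
        sizes["scapuloperoneal"] = max(4, n_patients // 2)
    diseases = [
        DiseaseSpec(
            name=name, prototype=proto, n_patients=sizes[name],
            age_mean=_AGE_MEANS[name],
            sex_ratio_f=0.35 if name == "pelvifemoral" else 0.5,
            asymmetry_sd=15.0 if name == "scapuloperoneal" else None,
        )
        for name, proto in _DISEASE_PROTOS.items()
    ]
    # studies recruit the diseases they can image: the thigh-only source
    # (no lower leg) does not contribute distal myopathies, and the source
    # missing the deep pelvis does not contribute the posterior-pelvic
    # pattern — mirroring how real multi-study pools are assembled.
    distal = ("anterior_distal", "posterior_distal", "scapuloperoneal")
    m14_weights = {d: 1.0 for d in _DISEASE_PROTOS if d not in distal}
    m05_weights = {d: 1.0 for d in _DISEASE_PROTOS if d != "posterior_pelvic"}
    sources = [
        SourceSpec("src_m04", "0-4", "bilateral", _observed()),
        SourceSpec("src_m05", "0-5", "average", _observed(_UPPER_PELVIS),
                   disease_weights=m05_weights),
        SourceSpec("src_m14", "1-4", "unilateral", _observed(_LOWER_LEG),
                   disease_weights=m14_weights),
        SourceSpec("src_2a2b", "2a2b", "bilateral", _observed()),
        SourceSpec("src_ff", "FF", "bilateral", _observed()),
    ]
    return CohortSpec(diseases=diseases, sources=sources)


#: Involvement families for the confounded design: two weight-permuted
#: variants of each family are bound to *different* scales, so no single
#: muscle identifies a scale through the disease, while multivariate weight
#: order still separates the variants.
_FAMILY_MUSCLES: dict[str, list[str]] = {
    "pelvic": ["gluteus_maximus", "adductor_magnus", "gluteus_medius",
               "adductor_longus", "pectineus"],
    "post_thigh": ["semimembranosus", "bflh", "semitendinosus", "bfsh",
                   "gracilis"],
    "ant_distal": ["tibialis_anterior", "extensors", "peronei", "fhl", "fdl"],
    "post_distal": ["soleus", "gastrocnemius_medialis",
                    "gastrocnemius_lateralis", "tibialis_posterior", "fdl"],
}
_VARIANT_WEIGHTS = {"a": [0.95, 0.90, 0.85, 0.80, 0.75],
                    "b": [0.88, 0.95, 0.79, 0.86, 0.77]}
_CONFOUNDED_BINDING = {
    "pelvic_a": "0-4", "pelvic_b": "0-5",
    "ant_distal_a": "0-4", "ant_distal_b": "0-5",
    "post_thigh_a": "1-4", "post_thigh_b": "FF",
    "post_distal_a": "1-4", "post_distal_b": "FF",
}
#: one marker muscle unscored per scale (none for 0-4): the source-wise
#: missing blocks from which the scale is trivially recoverable pre-harmonization
_CONFOUNDED_BLOCKS = {"0-4": (), "0-5": ("fhl",), "1-4": ("piriformis",),
                      "FF": ("gluteus_minimus",)}


def confounded_specs(n_patients: int = 50) -> CohortSpec:
    """Each disease observed through exactly one source: the scoring scale is
    confounded with the diagnosis.  Sources carry distinct missing-muscle
    blocks (the channel through which absolute scores betray their origin),
    and diseases come in weight-permuted family pairs split across scales."""
    diseases = []
    sources = []
    for name, scale in _CONFOUNDED_BINDING.items():
        family, variant = name.rsplit("_", 1)
        proto = _proto(**dict(zip(_FAMILY_MUSCLES[family],
                                  _VARIANT_WEIGHTS[variant])))
        diseases.append(DiseaseSpec(
            name=name, prototype=proto, n_patients=n_patients, age_mean=40.0))
        sources.append(SourceSpec(
            name=f"src_{name}", scale=scale, side_mode="bilateral",
            observed_muscles=_observed(_CONFOUNDED_BLOCKS[scale]),
            disease_weights={name: 1.0},
        ))
    return CohortSpec(diseases=diseases, sources=sources)
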