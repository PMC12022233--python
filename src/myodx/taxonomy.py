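"""Muscle taxonomy: canonical lower-limb muscle names and group membership.

Different studies report fat scores at different granularities — one source
scores *peroneus longus* and *peroneus brevis* separately, another reports a
single *peronei* score.  The taxonomy records which canonical muscles each
group contains so cohorts can be projected onto a shared feature space with
two operations: merging (average members into the group) and expansion (copy
a group score to every member).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class MuscleTaxonomy:
    """Canonical muscle vocabulary plus group -> members relations."""

    muscles: frozenset[str]
    groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"group {name!r} has no members")
            if name in members:
                raise ValueError(f"group {name!r} contains itself")
            unknown = members - self.muscles
            if unknown:
                raise ValueError(
                    f"group {name!r} has non-canonical members: {sorted(unknown)}"
                )
            if name in self.muscles:
                raise ValueError(f"group {name!r} collides with a muscle name")

    @property
    def names(self) -> frozenset[str]:
        """All valid score-column names: muscles plus groups."""
        return self.muscles | set(self.groups)

    def members(self, group: str) -> frozenset[str]:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(
                f"unknown muscle group {group!r}; known: {sorted(self.groups)}"
            ) from None

    def group_of(self, muscle: str) -> str | None:
        """The group containing ``muscle``, or None.  Groups do not overlap
        in the default taxonomy; with overlapping custom groups the first in
        sorted order wins (deterministic)."""
        for name in sorted(self.groups):
            if muscle in self.groups[name]:
                return name
        return None

    def validate_name(self, name: str) -> None:
        if name not in self.names:
            raise KeyError(f"{name!r} is neither a canonical muscle nor a group")

    def to_dict(self) -> dict:
        return {
            "muscles": sorted(self.muscles),
            "groups": {g: sorted(m) for g, m in sorted(self.groups.items())},
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def from_dict(cls, data: dict) -> "MuscleTaxonomy":
        return cls(
            muscles=frozenset(data["muscles"]),
            groups={g: frozenset(m) for g, m in data.get("groups", {}).items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "MuscleTaxonomy":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


_DEFAULT_MUSCLES = [
    # pelvis
    "gluteus_maximus", "gluteus_medius", "gluteus_minimus",
    "piriformis", "obturator_externus", "obturator_internus",
    "pectineus", "quadratus_femoris",
    "adductor_magnus", "adductor_longus", "adductor_brevis",
    "psoas", "iliacus", "tensor_fasciae_latae",
    # thigh
    "rectus_femoris", "vastus_lateralis", "vastus_medialis",
    "vastus_intermedius", "sartorius", "gracilis",
    "semimembranosus", "semitendinosus", "bflh", "bfsh",
    # lower leg
    "tibialis_anterior", "tibialis_posterior",
    "peroneus_longus", "peroneus_brevis",
    "gastrocnemius_medialis", "gastrocnemius_lateralis", "soleus",
    "fhl", "fdl",
    "extensor_digitorum_longus", "extensor_hallucis_longus",
]

_DEFAULT_GROUPS = {
    "glutei": ["gluteus_maximus", "gluteus_medius", "gluteus_minimus"],
    "obturators": ["obturator_externus", "obturator_internus"],
    "adductors": ["adductor_magnus", "adductor_longus", "adductor_brevis"],
    "iliopsoas": ["psoas", "iliacus"],
    "quadriceps": ["rectus_femoris", "vastus_lateralis", "vastus_medialis",
                   "vastus_intermedius"],
    "hamstrings": ["semimembranosus", "semitendinosus", "bflh", "bfsh"],
    "biceps_femoris": ["bflh", "bfsh"],
    "peronei": ["peroneus_longus", "peroneus_brevis"],
    "gastrocnemii": ["gastrocnemius_medialis", "gastrocnemius_lateralis"],
    "extensors": ["extensor_digitorum_longus", "extensor_hallucis_longus"],
}


def default_taxonomy() -> MuscleTaxonomy:
    """The default lower-limb taxonomy (pelvis, thigh and lower leg).

    Users with additional muscles or different grouping conventions can load
    their own taxonomy file; this is the set the default models are built on.
    """
    return MuscleTaxonomy(
        muscles=frozenset(_DEFAULT_MUSCLES),
        groups={g: frozenset(m) for g, m in _DEFAULT_GROUPS.items()},
    )


#: Default model feature space: individual muscles where sources commonly
#: report them, grouped peronei/extensors (commonly reported only as groups).
DEFAULT_TARGET_MUSCLES: list[str] = [
    "gluteus_maximus", "gluteus_medius", "gluteus_minimus",
    "piriformis", "obturator_externus", "obturator_internus",
    "pectineus", "quadratus_femoris",
    "adductor_magnus", "adductor_longus",
    "iliopsoas", "tensor_fasciae_latae",
    "rectus_femoris", "vastus_lateralis", "vastus_medialis",
    "vastus_intermedius", "sartorius", "gracilis",
    "semimembranosus", "semitendinosus", "bflh", "bfsh",
    "tibialis_anterior", "tibialis_posterior", "peronei",
    "gastrocnemius_medialis", "gastrocnemius_lateralis", "soleus",
    "fhl", "fdl", "extensors",
]
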